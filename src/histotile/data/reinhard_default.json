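{"brightness_standardize": true, "mask_white": false, "method": "reinhard", "target_means": [40.00179202216113, 33.291507175559445, -31.99688034565221], "target_stds": [24.43108656871722, 16.38322473651001, 11.794933822416823], "version": 1}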