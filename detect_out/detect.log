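INFO spineslip: spineslip 0.1.0 | python 3.11.15
INFO spineslip: config: {"extension": null, "flexion": null, "geometry": null, "k1": null, "k2": null, "k3": null, "mask": null}
INFO spineslip: spineslip 0.1.0 | python 3.11.15
INFO spineslip: config: {"junction": "L3L4", "n_cases": null, "noise_sd": null, "positive_rate": 0.5, "seed": 0, "slip": 0.25, "tilt": null}
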