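tree,category,proportion
survival_SR,survival_SR:yes,0.85
survival_SR,survival_SR:no,0.15
pleasantness_SR,pleasantness_SR:yes,0.81
pleasantness_SR,pleasantness_SR:no,0.19
foil_SR,foil_SR:yes,0.17
foil_SR,foil_SR:no,0.83
survival_PR,survival_PR:yes,0.81
survival_PR,survival_PR:no,0.19
pleasantness_PR,pleasantness_PR:yes,0.84
pleasantness_PR,pleasantness_PR:no,0.16
foil_PR,foil_PR:yes,0.17
foil_PR,foil_PR:no,0.83
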