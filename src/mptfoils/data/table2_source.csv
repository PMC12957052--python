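tree,category,proportion
survival_SR,survival_SR:survival,0.70
survival_SR,survival_SR:moving,0.11
survival_SR,survival_SR:no,0.19
moving_SR,moving_SR:survival,0.23
moving_SR,moving_SR:moving,0.51
moving_SR,moving_SR:no,0.26
foil_SR,foil_SR:survival,0.07
foil_SR,foil_SR:moving,0.08
foil_SR,foil_SR:no,0.85
survival_MR,survival_MR:survival,0.61
survival_MR,survival_MR:moving,0.17
survival_MR,survival_MR:no,0.22
moving_MR,moving_MR:survival,0.17
moving_MR,moving_MR:moving,0.61
moving_MR,moving_MR:no,0.23
foil_MR,foil_MR:survival,0.06
foil_MR,foil_MR:moving,0.11
foil_MR,foil_MR:no,0.84
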