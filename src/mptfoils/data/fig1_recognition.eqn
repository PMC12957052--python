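# Two-high-threshold recognition model, three word types x two retrieval conditions
# (_SR survival-constrained, _PR pleasantness-constrained retrieval)
survival_SR      survival_SR:yes      D_Survival_SR
survival_SR      survival_SR:yes      (1-D_Survival_SR)*b_SR
survival_SR      survival_SR:no       (1-D_Survival_SR)*(1-b_SR)
pleasantness_SR  pleasantness_SR:yes  D_Pleasantness_SR
pleasantness_SR  pleasantness_SR:yes  (1-D_Pleasantness_SR)*b_SR
pleasantness_SR  pleasantness_SR:no   (1-D_Pleasantness_SR)*(1-b_SR)
foil_SR          foil_SR:no           D_Foil_SR
foil_SR          foil_SR:yes          (1-D_Foil_SR)*b_SR
foil_SR          foil_SR:no           (1-D_Foil_SR)*(1-b_SR)
survival_PR      survival_PR:yes      D_Survival_PR
survival_PR      survival_PR:yes      (1-D_Survival_PR)*b_PR
survival_PR      survival_PR:no       (1-D_Survival_PR)*(1-b_PR)
pleasantness_PR  pleasantness_PR:yes  D_Pleasantness_PR
pleasantness_PR  pleasantness_PR:yes  (1-D_Pleasantness_PR)*b_PR
pleasantness_PR  pleasantness_PR:no   (1-D_Pleasantness_PR)*(1-b_PR)
foil_PR          foil_PR:no           D_Foil_PR
foil_PR          foil_PR:yes          (1-D_Foil_PR)*b_PR
foil_PR          foil_PR:no           (1-D_Foil_PR)*(1-b_PR)
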