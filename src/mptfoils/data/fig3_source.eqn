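# Two-high-threshold source-monitoring model, three word types x two retrieval conditions
# (_SR survival-constrained, _MR moving-constrained retrieval)
survival_SR  survival_SR:survival  D_Survival_SR*d_Survival_SR
survival_SR  survival_SR:survival  D_Survival_SR*(1-d_Survival_SR)*g_SR
survival_SR  survival_SR:moving    D_Survival_SR*(1-d_Survival_SR)*(1-g_SR)
survival_SR  survival_SR:survival  (1-D_Survival_SR)*b_SR*g_SR
survival_SR  survival_SR:moving    (1-D_Survival_SR)*b_SR*(1-g_SR)
survival_SR  survival_SR:no        (1-D_Survival_SR)*(1-b_SR)
moving_SR    moving_SR:moving      D_Moving_SR*d_Moving_SR
moving_SR    moving_SR:survival    D_Moving_SR*(1-d_Moving_SR)*g_SR
moving_SR    moving_SR:moving      D_Moving_SR*(1-d_Moving_SR)*(1-g_SR)
moving_SR    moving_SR:survival    (1-D_Moving_SR)*b_SR*g_SR
moving_SR    moving_SR:moving      (1-D_Moving_SR)*b_SR*(1-g_SR)
moving_SR    moving_SR:no          (1-D_Moving_SR)*(1-b_SR)
foil_SR      foil_SR:no            D_Foil_SR
foil_SR      foil_SR:survival      (1-D_Foil_SR)*b_SR*g_SR
foil_SR      foil_SR:moving        (1-D_Foil_SR)*b_SR*(1-g_SR)
foil_SR      foil_SR:no            (1-D_Foil_SR)*(1-b_SR)
survival_MR  survival_MR:survival  D_Survival_MR*d_Survival_MR
survival_MR  survival_MR:survival  D_Survival_MR*(1-d_Survival_MR)*g_MR
survival_MR  survival_MR:moving    D_Survival_MR*(1-d_Survival_MR)*(1-g_MR)
survival_MR  survival_MR:survival  (1-D_Survival_MR)*b_MR*g_MR
survival_MR  survival_MR:moving    (1-D_Survival_MR)*b_MR*(1-g_MR)
survival_MR  survival_MR:no        (1-D_Survival_MR)*(1-b_MR)
moving_MR    moving_MR:moving      D_Moving_MR*d_Moving_MR
moving_MR    moving_MR:survival    D_Moving_MR*(1-d_Moving_MR)*g_MR
moving_MR    moving_MR:moving      D_Moving_MR*(1-d_Moving_MR)*(1-g_MR)
moving_MR    moving_MR:survival    (1-D_Moving_MR)*b_MR*g_MR
moving_MR    moving_MR:moving      (1-D_Moving_MR)*b_MR*(1-g_MR)
moving_MR    moving_MR:no          (1-D_Moving_MR)*(1-b_MR)
foil_MR      foil_MR:no            D_Foil_MR
foil_MR      foil_MR:survival      (1-D_Foil_MR)*b_MR*g_MR
foil_MR      foil_MR:moving        (1-D_Foil_MR)*b_MR*(1-g_MR)
foil_MR      foil_MR:no            (1-D_Foil_MR)*(1-b_MR)
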