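cause,onset,closure,corrective
TT4: Periodic calibration,2022-06-16,2022-08-04,Calibration
TT4: Reagent replacement batch number,2022-08-13,2022-08-19,Calibration
AMH: Reagent replacement batch number,2022-06-06,2022-07-28,Calibration
ALT: Replace the new reagent brand,2022-09-21,2022-09-27,Use old brand reagents
ALT: Replace the new reagent brand,2022-10-09,2022-10-31,"Uncorrected, re-verify the data"
TC: Change calibrator batch number,2022-08-03,2022-08-25,Replace the calibrator and back-test samples
TC: Reagent has a long bottle opening time,2022-09-22,2022-10-31,Replacement reagent
UREA: Reagent replacement batch number,2022-06-01,2022-06-10,Calibration
ALB: Reagent replacement batch number,2022-06-27,2022-06-30,Calibration
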