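# Example horizontal PSSM records (synthetic counts, for demonstration and
# testing only; same layout as FlyFactorSurvey horizontal PSSM files).
>GAF_pwm
A |  2 18  1 17  2 16
C |  1  1  1  1  1  2
G | 16  0 17  1 16  1
T |  1  1  1  1  1  1
>PHO_pwm
A |  1  1  2 16  1 14
C |  2 16 15  1  2  2
G | 15  2  2  1  1  2
T |  2  1  1  2 16  2
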