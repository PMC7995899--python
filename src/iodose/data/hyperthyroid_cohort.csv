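# Literature summary values for a cohort of 15 hyperthyroid patients treated
# with I-131 after a four-point pre-therapeutic uptake protocol (3, 24, 48 h
# and one measurement between 3 and 9 days).  Per-patient thyroid TIAC,
# effective dose with and without the thyroid tissue weight, and female organ
# absorbed-dose coefficients.  The underlying raw uptake measurements were
# not published; this table serves as a regression fixture for cohort
# summary arithmetic only.
# units: tiac_h in MBq.h/MBq; ed, ed_no_thyroid in mSv/MBq; organ columns in mGy/MBq
patient_id,tiac_h,ed,ed_no_thyroid,thyroid,stomach_wall,kidneys,urinary_bladder_wall,uterus
1,107,23,0.53,620,0.43,1.05,0.17,0.14
2,148,32,0.54,854,0.32,0.57,0.11,0.09
3,107,23,0.46,622,0.38,0.67,0.14,0.11
4,170,37,0.64,981,0.32,0.81,0.12,0.11
5,128,28,0.53,742,0.36,0.76,0.14,0.11
6,98,21,0.70,564,0.56,1.99,0.23,0.24
7,67,15,0.30,390,0.39,0.38,0.15,0.09
8,75,16,0.35,431,0.40,0.54,0.15,0.10
9,89,19,0.32,517,0.34,0.19,0.12,0.06
10,125,27,0.68,724,0.47,1.57,0.19,0.19
11,114,25,0.43,658,0.35,0.47,0.13,0.08
12,116,25,0.53,669,0.40,0.94,0.16,0.13
13,77,17,0.03,446,0.35,0.16,0.13,0.06
14,106,23,0.39,616,0.34,0.35,0.12,0.07
15,166,36,0.68,961,0.35,1.05,0.13,0.13
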