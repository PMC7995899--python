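# iodose SYNTHETIC fixture S-value table for I-131 (+ Xe-131m) — not
# phantom Monte Carlo output; self-dose particle terms are mean electron
# energy per decay over reference organ mass, photon cross terms use
# assumed absorbed fractions.  Exercises the dose pipeline only; supply
# an authoritative table for clinical or regulatory use.
# units: mGy/(MBq.h)
nuclide,source,target,sex,s_photon,s_particle
I-131,thyroid,thyroid,male,0.278124,4.88811
I-131,blood,thyroid,male,0.00370832,0
I-131,other,thyroid,male,0.00278124,0
I-131,thyroid,thyroid,female,0.333749,5.86574
I-131,blood,thyroid,female,0.00444998,0
I-131,other,thyroid,female,0.00333749,0
I-131,thyroid,stomach_wall,male,0.00144624,0
I-131,stomach_contents,stomach_wall,male,0.0867747,0.190636
I-131,stomach_wall,stomach_wall,male,0.0867747,0.762546
I-131,kidneys,stomach_wall,male,0.01157,0
I-131,blood,stomach_wall,male,0.00289249,0
I-131,other,stomach_wall,male,0.00289249,0
I-131,thyroid,stomach_wall,female,0.00154955,0
I-131,stomach_contents,stomach_wall,female,0.0929729,0.204253
I-131,stomach_wall,stomach_wall,female,0.0929729,0.817013
I-131,kidneys,stomach_wall,female,0.0123964,0
I-131,blood,stomach_wall,female,0.0030991,0
I-131,other,stomach_wall,female,0.0030991,0
I-131,thyroid,kidneys,male,0.000349898,0
I-131,stomach_contents,kidneys,male,0.00699796,0
I-131,stomach_wall,kidneys,male,0.00699796,0
I-131,kidneys,kidneys,male,0.0489857,0.368974
I-131,urinary_bladder_contents,kidneys,male,0.00139959,0
I-131,blood,kidneys,male,0.00279918,0
I-131,other,kidneys,male,0.00209939,0
I-131,thyroid,kidneys,female,0.00039443,0
I-131,stomach_contents,kidneys,female,0.00788861,0
I-131,stomach_wall,kidneys,female,0.00788861,0
I-131,kidneys,kidneys,female,0.0552203,0.415934
I-131,urinary_bladder_contents,kidneys,female,0.00157772,0
I-131,blood,kidneys,female,0.00315544,0
I-131,other,kidneys,female,0.00236658,0
I-131,thyroid,urinary_bladder_wall,male,0.000867747,0
I-131,urinary_bladder_contents,urinary_bladder_wall,male,0.173549,0.571909
I-131,blood,urinary_bladder_wall,male,0.00347099,0
I-131,other,urinary_bladder_wall,male,0.00347099,0
I-131,thyroid,urinary_bladder_wall,female,0.00108468,0
I-131,urinary_bladder_contents,urinary_bladder_wall,female,0.216937,0.714887
I-131,blood,urinary_bladder_wall,female,0.00433873,0
I-131,other,urinary_bladder_wall,female,0.00433873,0
I-131,thyroid,uterus,female,0.000542342,0
I-131,stomach_contents,uterus,female,0.00271171,0
I-131,urinary_bladder_contents,uterus,female,0.0406756,0
I-131,blood,uterus,female,0.00271171,0
I-131,other,uterus,female,0.00271171,0
Xe-131m,thyroid,thyroid,male,0.00338973,3.39784
Xe-131m,blood,thyroid,male,4.51964e-05,0
Xe-131m,other,thyroid,male,3.38973e-05,0
Xe-131m,thyroid,thyroid,female,0.00406768,4.07741
Xe-131m,blood,thyroid,female,5.42357e-05,0
Xe-131m,other,thyroid,female,4.06768e-05,0
Xe-131m,thyroid,stomach_wall,male,1.76266e-05,0
Xe-131m,stomach_contents,stomach_wall,male,0.0010576,0.132516
Xe-131m,stomach_wall,stomach_wall,male,0.0010576,0.530063
Xe-131m,kidneys,stomach_wall,male,0.000141013,0
Xe-131m,blood,stomach_wall,male,3.52532e-05,0
Xe-131m,other,stomach_wall,male,3.52532e-05,0
Xe-131m,thyroid,stomach_wall,female,1.88857e-05,0
Xe-131m,stomach_contents,stomach_wall,female,0.00113314,0.141981
Xe-131m,stomach_wall,stomach_wall,female,0.00113314,0.567925
Xe-131m,kidneys,stomach_wall,female,0.000151085,0
Xe-131m,blood,stomach_wall,female,3.77713e-05,0
Xe-131m,other,stomach_wall,female,3.77713e-05,0
Xe-131m,thyroid,kidneys,male,4.2645e-06,0
Xe-131m,stomach_contents,kidneys,male,8.52901e-05,0
Xe-131m,stomach_wall,kidneys,male,8.52901e-05,0
Xe-131m,kidneys,kidneys,male,0.00059703,0.256482
Xe-131m,urinary_bladder_contents,kidneys,male,1.7058e-05,0
Xe-131m,blood,kidneys,male,3.4116e-05,0
Xe-131m,other,kidneys,male,2.5587e-05,0
Xe-131m,thyroid,kidneys,female,4.80726e-06,0
Xe-131m,stomach_contents,kidneys,female,9.61452e-05,0
Xe-131m,stomach_wall,kidneys,female,9.61452e-05,0
Xe-131m,kidneys,kidneys,female,0.000673016,0.289125
Xe-131m,urinary_bladder_contents,kidneys,female,1.9229e-05,0
Xe-131m,blood,kidneys,female,3.84581e-05,0
Xe-131m,other,kidneys,female,2.88436e-05,0
Xe-131m,thyroid,urinary_bladder_wall,male,1.0576e-05,0
Xe-131m,urinary_bladder_contents,urinary_bladder_wall,male,0.00211519,0.397547
Xe-131m,blood,urinary_bladder_wall,male,4.23039e-05,0
Xe-131m,other,urinary_bladder_wall,male,4.23039e-05,0
Xe-131m,thyroid,urinary_bladder_wall,female,1.322e-05,0
Xe-131m,urinary_bladder_contents,urinary_bladder_wall,female,0.00264399,0.496934
Xe-131m,blood,urinary_bladder_wall,female,5.28798e-05,0
Xe-131m,other,urinary_bladder_wall,female,5.28798e-05,0
Xe-131m,thyroid,uterus,female,6.60998e-06,0
Xe-131m,stomach_contents,uterus,female,3.30499e-05,0
Xe-131m,urinary_bladder_contents,uterus,female,0.000495749,0
Xe-131m,blood,uterus,female,3.30499e-05,0
Xe-131m,other,uterus,female,3.30499e-05,0
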