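# iodose nuclide registry — format v1 (2025-09 transcription)
#
# Provenance: half-lives, branching fractions and principal emission lines
# transcribed from standard published decay-data compilations.  Emission
# spectra are CONDENSED: minor lines are aggregated into representative
# mean-energy rows per radiation class (photon / electron).  They are
# adequate for S-value composition against coarse SAF grids and for the
# mean-energy-per-decay constant used in activity planning, not for
# spectroscopy.
#
# Record types (tab-separated):
#   N  symbol   half_life_days        "stable" marks a stable nuclide
#   P  parent   daughter  branching_fraction_in_[0,1]
#   E  symbol   class     energy_MeV  yield_per_decay
#
# Energies are mean energies per transition in MeV (converted to joule at
# load time); yields are per nuclear transformation.  Users may extend the
# registry with additional iodine isotopes by appending records in the same
# format and pointing the loader at the extra file.

N	I-131	8.0252
N	Xe-131m	11.84
N	Xe-131	stable
N	I-123	0.55098
N	Te-123	stable
N	I-124	4.1760
N	Te-124	stable
N	I-125	59.400
N	Te-125	stable

P	I-131	Xe-131m	0.0118
P	I-131	Xe-131	0.9882
P	Xe-131m	Xe-131	1.0
P	I-123	Te-123	1.0
P	I-124	Te-124	1.0
P	I-125	Te-125	1.0

# I-131: beta-minus; aggregate beta row (mean energy over all branches),
# principal gammas, K-conversion electron of the 364.5 keV line, X-rays.
E	I-131	electron	0.1916	1.000
E	I-131	electron	0.3297	0.0155
E	I-131	electron	0.0457	0.0350
E	I-131	photon	0.36449	0.8150
E	I-131	photon	0.63699	0.0716
E	I-131	photon	0.28431	0.0612
E	I-131	photon	0.08019	0.0262
E	I-131	photon	0.72291	0.0177
E	I-131	photon	0.0295	0.0390

# Xe-131m: isomeric transition, heavily converted 163.9 keV line.
E	Xe-131m	photon	0.16393	0.0196
E	Xe-131m	photon	0.0300	0.0457
E	Xe-131m	electron	0.1290	0.6090
E	Xe-131m	electron	0.1596	0.2845
E	Xe-131m	electron	0.1634	0.0572
E	Xe-131m	electron	0.0252	0.1800

# I-123: electron capture; 159 keV gamma, Te X-rays, conversion and
# aggregated Auger electrons.
E	I-123	photon	0.15900	0.8330
E	I-123	photon	0.0274	0.7060
E	I-123	photon	0.0313	0.1520
E	I-123	photon	0.52900	0.0139
E	I-123	electron	0.1274	0.1360
E	I-123	electron	0.1546	0.0178
E	I-123	electron	0.0035	3.3000

# I-124: electron capture / beta-plus; aggregate positron row plus
# annihilation photons and principal gammas.
E	I-124	photon	0.60270	0.6280
E	I-124	photon	0.72280	0.1036
E	I-124	photon	1.69090	0.1044
E	I-124	photon	0.51100	0.4500
E	I-124	photon	0.0274	0.5000
E	I-124	electron	0.8200	0.2280
E	I-124	electron	0.0050	1.0000

# I-125: electron capture; 35.5 keV gamma, Te X-rays, conversion and
# aggregated Auger electrons.
E	I-125	photon	0.03549	0.0668
E	I-125	photon	0.0274	1.1500
E	I-125	photon	0.0313	0.2540
E	I-125	electron	0.0305	0.1060
E	I-125	electron	0.0345	0.1270
E	I-125	electron	0.00045	14.000
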