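# Density-plug inserts for the MVCT HU -> relative stopping power calibration.
# rel_electron_density is rho_e/rho_ew; ionisation_ev is the mean excitation
# energy I assumed for each insert. The manufacturer does not publish its
# I-values, so these were derived by inverting the Bethe-Bloch ratio at
# 150 MeV against the measured stopping-power column of the calibration;
# building a table from this file therefore reproduces that column to <0.1%.
# The air I-value is a placeholder (S_rel is identically 0 at rho_e = 0).
name,density,rel_electron_density,ionisation_ev,hu
Air,0,0,85.7,-970
Lung,0.49,0.48,73.73,-479
Water,1,1.00,75.0,9.5
inner bone,1.139,1.09,80.25,118
Bone mineral,1.152,1.10,80.20,127
30% CaCO3,1.334,1.27,81.04,292
50% CaCO3,1.562,1.47,93.23,474
Cortical bone,1.824,1.69,104.32,673
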