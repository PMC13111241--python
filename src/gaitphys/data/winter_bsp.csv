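# Body-segment parameters, standard gait-analysis proportion table (Winter,
# Biomechanics and Motor Control of Human Movement, 4th ed., Tables 4.1/4.8).
# length_frac: segment length as fraction of stature H
# mass_frac: segment mass as fraction of total body mass (per side for paired segments)
# com_frac: centre-of-mass location from the proximal end, fraction of segment length
# gyration_frac: radius of gyration about the segment COM, fraction of segment length
# version: 1
segment,length_frac,mass_frac,com_frac,gyration_frac
pelvis_trunk,0.288,0.678,0.626,0.496
thigh,0.245,0.100,0.433,0.323
shank,0.246,0.0465,0.433,0.302
foot,0.152,0.0145,0.500,0.475
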