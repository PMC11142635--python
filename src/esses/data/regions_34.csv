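region,hemisphere,lobe_group
L-frontal-orbital,L,frontal
L-frontal-basal,L,frontal
L-frontal-parasagittal,L,frontal
L-frontal-periventricular,L,frontal
L-frontal-lateral,L,frontal
L-frontal-operculum,L,frontal
L-hippocampus,L,temporal
L-amygdala,L,temporal
L-uncus,L,temporal
L-temporal-anterior-neocortical,L,temporal
L-temporal-posterior-neocortical,L,temporal
L-gyrus-parahippocampalis,L,temporal
L-insula-anterior,L,insular
L-insula-posterior,L,insular
L-central,L,central
L-parietal,L,parietal
L-occipital,L,occipital
R-frontal-orbital,R,frontal
R-frontal-basal,R,frontal
R-frontal-parasagittal,R,frontal
R-frontal-periventricular,R,frontal
R-frontal-lateral,R,frontal
R-frontal-operculum,R,frontal
R-hippocampus,R,temporal
R-amygdala,R,temporal
R-uncus,R,temporal
R-temporal-anterior-neocortical,R,temporal
R-temporal-posterior-neocortical,R,temporal
R-gyrus-parahippocampalis,R,temporal
R-insula-anterior,R,insular
R-insula-posterior,R,insular
R-central,R,central
R-parietal,R,parietal
R-occipital,R,occipital
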