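term,class
cytoplasm,Cytoplasm
cytosol,Cytoplasm
cytoskeleton,Cytoplasm
perinuclear region,Cytoplasm
nucleus,Nucleus
nucleolus,Nucleus
nucleoplasm,Nucleus
nuclear envelope,Nucleus
nuclear speckle,Nucleus
chromosome,Nucleus
secreted,Extracellular
extracellular space,Extracellular
extracellular matrix,Extracellular
cell wall,Extracellular
cell membrane,Cell membrane
plasma membrane,Cell membrane
cell surface,Cell membrane
apical cell membrane,Cell membrane
basolateral cell membrane,Cell membrane
mitochondrion,Mitochondrion
mitochondrion matrix,Mitochondrion
mitochondrion inner membrane,Mitochondrion
mitochondrion outer membrane,Mitochondrion
mitochondrion intermembrane space,Mitochondrion
plastid,Plastid
chloroplast,Plastid
chloroplast stroma,Plastid
chloroplast thylakoid membrane,Plastid
chloroplast envelope,Plastid
amyloplast,Plastid
endoplasmic reticulum,Endoplasmic reticulum
endoplasmic reticulum membrane,Endoplasmic reticulum
endoplasmic reticulum lumen,Endoplasmic reticulum
sarcoplasmic reticulum,Endoplasmic reticulum
microsome,Endoplasmic reticulum
lysosome,Lysosome/Vacuole
lysosome membrane,Lysosome/Vacuole
vacuole,Lysosome/Vacuole
vacuole membrane,Lysosome/Vacuole
endosome,Lysosome/Vacuole
late endosome,Lysosome/Vacuole
golgi apparatus,Golgi apparatus
golgi apparatus membrane,Golgi apparatus
golgi stack,Golgi apparatus
trans-golgi network,Golgi apparatus
peroxisome,Peroxisome
peroxisome membrane,Peroxisome
peroxisome matrix,Peroxisome
glyoxysome,Peroxisome
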