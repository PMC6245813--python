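tissue	organ
adrenal	Adrenal
biceps	Muscle
brainstem	Brain
cerebellum	Brain
cerebrum	Brain
cortex	Kidney
drg	DRG
duodenum	Intestine
glandular_stomach	Stomach
heart	Heart
hippocampus	Brain
ileum	Intestine
jejunum	Intestine
kidney	Kidney
liver	Liver
medulla	Kidney
nonglandular_stomach	Stomach
ovary	Ovary
pancreas	Pancreas
soleus	Muscle
testicle	Testicle
uterus	Uterus
whole_blood	WholeBlood
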