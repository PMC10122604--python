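# Additional vocabulary backing the synthetic sentence generator.
# Columns: surface <TAB> category.
atelectasis	finding
effusion	finding
pleural effusion	finding
pneumothorax	finding
mass	finding
nodule	finding
lesion	finding
infiltrate	finding
cyst	finding
granuloma	finding
fibrosis	finding
scarring	finding
thickening	finding
calcification	finding
cardiomegaly	finding
emphysema	finding
infarct	finding
ischemia	finding
abscess	finding
malignancy	finding
infection	finding
tuberculosis	finding
sarcoidosis	finding
lymphoma	finding
metastasis	finding
aspiration	finding
hydrocephalus	finding
signal abnormality	finding
volume loss	finding
effacement	finding
fracture	finding
neoplasm	finding
degenerative changes	finding
air trapping	finding
trachea	anatomy
diaphragm	anatomy
mediastinum	anatomy
hilum	anatomy
pleura	anatomy
spleen	anatomy
liver	anatomy
kidney	anatomy
stomach	anatomy
bowel	anatomy
femur	anatomy
clavicle	anatomy
rib	anatomy
aorta	anatomy
heart	anatomy
thalamus	anatomy
pons	anatomy
skull	anatomy
spine	anatomy
abdomen	anatomy
pelvis	anatomy
bladder	anatomy
colon	anatomy
esophagus	anatomy
ventricle	anatomy
cortex	anatomy
frontal lobe	anatomy
temporal lobe	anatomy
cerebellum	anatomy
brainstem	anatomy
humerus	anatomy
scapula	anatomy
sternum	anatomy
bronchus	anatomy
lingula	anatomy
foot	anatomy
catheter	device
picc	device
line	device
tube	device
endotracheal tube	device
chest tube	device
feeding tube	device
nasogastric tube	device
drain	device
stent	device
pacemaker	device
wire	device
port	device
central line	device
suggestive of	hedge
worrisome for	hedge
compatible with	hedge
suspicious for	hedge
may represent	hedge
likely	certainty_descriptor
possible	certainty_descriptor
probable	certainty_descriptor
questionable	certainty_descriptor
positioned	position_status
advanced	position_status
placed	position_status
malpositioned	position_status
coiled	position_status
upper	location_descriptor
superior	location_descriptor
anterior	location_descriptor
posterior	location_descriptor
medial	location_descriptor
lateral	location_descriptor
proximal	location_descriptor
distal	location_descriptor
low	relative_position
midline	relative_position
patient motion	process
respiratory motion	process
swallowing	process
bowel peristalsis	process
recent instrumentation	process
breath hold	process
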