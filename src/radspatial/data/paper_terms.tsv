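# Radiological-entity terms printed in the schema / heuristics tables and
# worked example sentences.  Columns: surface <TAB> category.
opacity	finding
lung	anatomy
consistent with	hedge
hyaline membrane disease	finding
pic catheter	device
terminates	position_status
svc	anatomy
mid	location_descriptor
uv line	device
tip	position_status
high	relative_position
right	location_descriptor
atrium	anatomy
ett tube	device
carina	anatomy
increased signal	finding
lateral ventricle	anatomy
left	location_descriptor
corona radiata	anatomy
lacune	finding
movement of the right foot	process
cortical bold activation	finding
edema	finding
periventricular white matter	anatomy
white matter	anatomy
centrum semi-ovale	anatomy
microvascular angiopathy	finding
consolidation	finding
lobe	anatomy
lower	location_descriptor
concerning for	hedge
pneumonia	finding
atelactases	finding
inferior	location_descriptor
cerebellar peduncle	anatomy
inferior cerebellar peduncle	anatomy
hypodensity	finding
hemorrhage	finding
brain parenchyma	anatomy
atherosclerotic changes	finding
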