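element,code,value_mm
humerus,Bd,68.0
humerus,Bp,82.0
humerus,BT,63.0
humerus,DPA,52.0
humerus,GB,85.0
humerus,GL,238.0
humerus,SD,28.0
humerus,SDO,40.0
tibia,Bd,52.0
tibia,Bp,78.0
tibia,BT,48.0
tibia,DPA,46.0
tibia,GB,80.0
tibia,GL,312.0
tibia,SD,31.0
tibia,SDO,38.0
metatarsal,Bd,47.0
metatarsal,Bp,41.0
metatarsal,BT,44.0
metatarsal,DPA,36.0
metatarsal,GB,45.0
metatarsal,GL,201.0
metatarsal,SD,23.0
metatarsal,SDO,30.0
metacarpal,Bd,50.0
metacarpal,Bp,47.0
metacarpal,BT,46.0
metacarpal,DPA,38.0
metacarpal,GB,49.0
metacarpal,GL,178.0
metacarpal,SD,27.0
metacarpal,SDO,32.0
calcaneus,Bd,38.0
calcaneus,Bp,42.0
calcaneus,BT,36.0
calcaneus,DPA,44.0
calcaneus,GB,40.0
calcaneus,GL,116.0
calcaneus,SD,22.0
calcaneus,SDO,35.0
femur,Bd,78.0
femur,Bp,96.0
femur,BT,72.0
femur,DPA,58.0
femur,GB,98.0
femur,GL,305.0
femur,SD,29.0
femur,SDO,42.0
radius-ulna,Bd,61.0
radius-ulna,Bp,70.0
radius-ulna,BT,56.0
radius-ulna,DPA,54.0
radius-ulna,GB,72.0
radius-ulna,GL,264.0
radius-ulna,SD,33.0
radius-ulna,SDO,39.0
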