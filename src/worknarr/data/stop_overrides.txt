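# Words rescued from the stop list because they carry injury semantics:
# body parts, mechanisms of injury, and injurious objects.  These would
# otherwise be discarded as common English words.  User-extensible via
# configuration; entries are stemmed on load.
# body parts
back
face
feet
foot
head
hand
arm
leg
eye
knee
finger
shoulder
ankle
wrist
hip
neck
chest
# mechanisms of injury
cut
fall
fell
burn
crush
strain
twist
struck
slip
trip
# injurious objects
saw
knife
glass
nail
hammer
door
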