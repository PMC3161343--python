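# Default work-term index: stem<TAB>frequency<TAB>headings(;-separated)
# The first seven stems are the published work-specific index terms from
# the QISU ED-narrative study; the remainder are SYNTHETIC vocabulary
# matching this package's corpus generator (the full 50-term study index
# was never published).  Frequencies here are nominal sample counts for
# ordering only.  Supply your own index built from an annotated sample
# for real data (worknarr build-index).
job site	40	work location
factori	35	work location
mine	30	work location
forklift	28	object involved
construct	25	work location
labour	20	activity task
client	15	occupation
# --- synthetic generator vocabulary below this line ---
warehous	18	work location
scaffold	16	object involved
weld	15	activity task
crane	12	object involved
excav	12	object involved
abattoir	10	work location
apprentic	10	occupation
tradesman	8	occupation
har	12	safety/preventative devices
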