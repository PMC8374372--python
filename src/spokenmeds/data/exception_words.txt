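# Common-word-filter exceptions: words that stay annotated as medications even
# though they appear in the common-English word list. Three groups: 17 common
# single-token medication names, 6 generic medication-class terms, and "flu"
# (which names either a diagnosis or an immunization). Only "ambien" and
# "insulin" of the 17 are fixed by the published rule set; the other 15 are an
# editable package default.
ambien
insulin
aspirin
tylenol
advil
motrin
ibuprofen
benadryl
claritin
zyrtec
prozac
zoloft
xanax
valium
viagra
lipitor
penicillin
herb
herbs
supplement
supplements
vitamin
vitamins
flu
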