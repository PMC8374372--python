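"""Annotate one conversation and walk through the cascade's audit trail.

Builds a short clinician-patient exchange containing a true medication, an
exception-list survivor, an immunization mention, and two false-positive
traps, then prints what the pipeline kept, added and removed, and why.
"""

from spokenmeds import (
    Transcript,
    default_filter_config,
    load_default_lexicon,
    run_pipeline,
)

text = (
    "DR: Your labs came back fine today.\n"
    "PT: My ring is white gold, does that matter?\n"
    "DR: No. Did you get your flu shot this year?\n"
    "PT: Yes, and I still take my insulin and my lisinopril.\n"
)

result = run_pipeline(
    Transcript("demo", text), load_default_lexicon(), default_filter_config()
)

print("Final medication mentions:")
for a in result.final:
    print(f"  [{a.start:3d},{a.end:3d})  {a.covered_text!r:14s} via {a.provenance}")

print("\nRemovals and additions along the cascade:")
for rec in result.audit:
    if rec.action in ("removed", "added") and rec.stage != "match":
        print(f"  {rec.action:7s} {rec.annotation.covered_text!r:14s}"
              f" at stage {rec.stage} ({rec.reason})")

# 'today' (ToDAY, a veterinary antibiotic) falls to the common-word filter,
# 'gold' to the chemical-element filter; 'flu' is added because it shares a
# sentence with the trigger word 'shot'; 'insulin' survives the common-word
# filter only because it is on the 24-word exception list.
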