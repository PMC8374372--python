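"""Write pipeline output as Knowtator XML (eHOST) and JSON standoff.

Annotates a one-line transcript, emits both standoff formats plus a full
eHOST project directory, and reads the Knowtator file back to show the
round trip is lossless.
"""

import tempfile
from pathlib import Path

from spokenmeds import (
    Transcript,
    default_filter_config,
    load_default_lexicon,
    read_knowtator,
    run_pipeline,
    write_ehost_project,
    write_json,
    write_knowtator,
)

t = Transcript("visit01", "PT: I take lisinopril and metformin at night.\n")
result = run_pipeline(t, load_default_lexicon(), default_filter_config())

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    xml_path = write_knowtator(result.final, tmp / "visit01.txt.knowtator.xml")
    json_path = write_json(result.final, tmp / "visit01.json")
    write_ehost_project([(t, result.final)], tmp / "project")

    print("Knowtator XML:")
    print(xml_path.read_text())
    print("JSON standoff:")
    print(json_path.read_text())

    back = read_knowtator(xml_path)
    same = [(a.start, a.end, a.covered_text) for a in back] == \
        [(a.start, a.end, a.covered_text) for a in result.final]
    print(f"round trip lossless: {same}")
    print("eHOST layout:",
          sorted(p.relative_to(tmp).as_posix() for p in (tmp / "project").rglob("*")
                 if p.is_file()))

# Spans are 0-based with exclusive ends, indexing characters of the source
# text — the convention eHOST uses when scoring.
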