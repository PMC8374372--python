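#!/usr/bin/env python
"""Vendor the full 10 000-word common-English list into the package data.

Downloads the "google-10000-english" word list (the 10 000 most common
English words from Google's Trillion Word Corpus, as published at
https://github.com/first20hours/google-10000-english), verifies it has
exactly 10 000 entries, and writes it to
``src/spokenmeds/data/common_words_10k.txt`` with a provenance header.

Requires network access; the package otherwise falls back to the bundled
curated subset (``common_words_synthetic.txt``).  After vendoring, pass the
full list to :func:`spokenmeds.default_filter_config` via ``load_wordlist``
or rely on tooling that prefers ``common_words_10k.txt`` when present.
"""

from __future__ import annotations

import sys
import urllib.request
from pathlib import Path

URL = (
    "https://raw.githubusercontent.com/first20hours/"
    "google-10000-english/master/google-10000-english.txt"
)
DEST = (
    Path(__file__).resolve().parent.parent
    / "src" / "spokenmeds" / "data" / "common_words_10k.txt"
)


def main() -> int:
    print(f"fetching {URL}")
    with urllib.request.urlopen(URL, timeout=60) as resp:
        words = [w.strip() for w in resp.read().decode("utf-8").splitlines()
                 if w.strip()]
    if len(words) != 10_000:
        print(f"expected 10000 words, got {len(words)}; not writing", file=sys.stderr)
        return 1
    header = (
        "# The 10 000 most common English words from Google's Trillion Word\n"
        "# Corpus, vendored verbatim from\n"
        "# https://github.com/first20hours/google-10000-english\n"
        "# (data derived from Google's licensing-free n-gram corpus release).\n"
    )
    DEST.write_text(header + "\n".join(words) + "\n", encoding="utf-8")
    print(f"wrote {len(words)} words to {DEST}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
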