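import pytest

from spokenmeds import (
    Annotation,
    AnnotationSet,
    MEDICATION,
    default_filter_config,
    load_default_lexicon,
)


def make_ann(start, end, text="", label=MEDICATION, **kw):
    return Annotation(
        start=start, end=end, covered_text=text or "x" * (end - start),
        label=label, **kw,
    )


def make_set(spans, doc_id="doc", label=MEDICATION):
    return AnnotationSet(doc_id, [make_ann(s, e, label=label) for s, e in spans])


@pytest.fixture(scope="session")
def lexicon():
    return load_default_lexicon()


@pytest.fixture(scope="session")
def config():
    return default_filter_config()
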