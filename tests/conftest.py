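import os
import sys

import pytest

sys.path.insert(0, os.path.dirname(__file__))

from fctmap.evaluation import AnnotatedMatch  # noqa: E402


@pytest.fixture
def toy_annotated():
    """Six annotated pairs spanning both labels and both item classes."""
    return [
        AnnotatedMatch("q1", "c1", 95, ediff=2.0, c5_probability=0.98,
                       label="plausible", item_class="directly_mappable"),
        AnnotatedMatch("q2", "c2", 88, ediff=25.0, c5_probability=0.52,
                       label="non_plausible", item_class="directly_mappable"),
        AnnotatedMatch("q3", "c3", 70, ediff=1.0, c5_probability=0.90,
                       label="plausible", item_class="other"),
        AnnotatedMatch("q4", "c4", 56, ediff=1.5, c5_probability=0.95,
                       label="plausible", item_class="other"),
        AnnotatedMatch("q5", "c5", 45, ediff=None, c5_probability=0.20,
                       label="non_plausible", item_class="other"),
        AnnotatedMatch("q6", "c6", 30, ediff=80.0, c5_probability=0.05,
                       label="non_plausible", item_class="directly_mappable"),
    ]
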