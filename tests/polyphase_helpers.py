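"""Small helpers shared by phasing-related tests."""
from polyploidkit.benchmarks import best_assignment_accuracy  # noqa: F401
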