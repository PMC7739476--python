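import sys
from pathlib import Path

from hypothesis import settings

# oracles.py lives next to the tests
sys.path.insert(0, str(Path(__file__).parent))

# property tests must be reproducible run-to-run
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
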