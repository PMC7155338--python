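import os
import sys

# make tests/helpers.py importable regardless of invocation directory
sys.path.insert(0, os.path.dirname(__file__))
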