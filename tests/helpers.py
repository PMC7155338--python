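"""Shared shorthand for the test suite."""

from rfplus import parse_newick


def rooted(text: str):
    return parse_newick(text, rooted=True)


def unrooted(text: str):
    return parse_newick(text, rooted=False)
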