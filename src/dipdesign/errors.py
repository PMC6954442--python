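"""Exception hierarchy shared across design modules."""


class DesignError(ValueError):
    """A design constraint cannot be satisfied."""


class InfeasibleError(DesignError):
    """No solution exists within the search budget; the message names the clash."""


class SwapError(DesignError):
    """No synonymous codon removes a banned motif (e.g. Met/Trp single-codon)."""
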