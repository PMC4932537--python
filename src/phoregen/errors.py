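"""Exception hierarchy for phoregen."""


class PhoregenError(Exception):
    """Base class for all package errors."""


class ParseError(PhoregenError):
    """Malformed structure input (SMILES string or SDF record)."""


class UnsupportedElementError(PhoregenError):
    """Element outside the supported organic subset {H,C,N,O,S,F,Cl,Br}."""


class UnsupportedChargeError(PhoregenError):
    """Formula charge outside the +/-1 range handled by m/z conventions."""


class EmbeddingError(PhoregenError):
    """3D embedding failed after the configured number of restarts."""


class NoConsensusError(PhoregenError):
    """Pharmacophore elucidation found no cluster reaching min_coverage."""

    def __init__(self, best_coverage: float, min_coverage: float):
        self.best_coverage = best_coverage
        self.min_coverage = min_coverage
        super().__init__(
            f"no consensus cluster reached coverage {min_coverage:.3f} "
            f"(best found: {best_coverage:.3f})"
        )
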