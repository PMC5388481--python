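"""Exception hierarchy for the barcode evaluation pipeline."""


class BarcodeEvalError(Exception):
    """Base class for all pipeline errors."""


class InputError(BarcodeEvalError):
    """Malformed or inconsistent user input (metadata, ids, config)."""


class AlignmentError(InputError):
    """Sequence matrix is not a valid alignment (ragged rows, empty file)."""


class UndefinedDistanceError(BarcodeEvalError):
    """A pairwise distance is not defined.

    Raised when two sequences share no comparable site after pairwise
    deletion, or when the K2P logarithms are taken on a non-positive
    argument (substitutional saturation).
    """


class TreeError(BarcodeEvalError):
    """Tree construction or tree query is impossible on this input."""
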