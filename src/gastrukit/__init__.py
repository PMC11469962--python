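"""gastrukit: computational staging and comparison of embryo models.

Tools for placing gastruloid/embryo scRNA-seq datasets on a reference
developmental-time axis, mapping cell types across datasets by reciprocal
non-negative least squares, testing inter-individual composition
variability, classifying cross-species pseudotime gene dynamics, and
applying rule-based somite morphometrics — together with a synthetic-data
generator that plants the structure these analyses assume.
"""

from .containers import (
    CellMatrix,
    FormatError,
    IntensityProfile,
    OrthologMap,
    PseudobulkMatrix,
)

__version__ = "0.1.0"

__all__ = [
    "CellMatrix",
    "PseudobulkMatrix",
    "OrthologMap",
    "IntensityProfile",
    "FormatError",
    "stage_seed",
]


def stage_seed(seed: int, stage: str) -> int:
    """Fan a global seed out to a per-stage seed (stable blake2s hash)."""
    import hashlib

    h = hashlib.blake2s(f"{seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(h, "little") % (2**31)
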