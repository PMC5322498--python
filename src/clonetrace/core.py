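"""Shared vocabulary for clonal barcode tracking.

Four haematopoietic read-outs are tracked per transplanted mouse: peripheral
B cells, T cells, myeloid cells and bone-marrow erythroid progenitors
(CFU-E).  A clone (one barcode in one mouse) is typed by the subset of
lineages in which it is detected; the 15 non-empty subsets are the clone
types.  Labels list lineages in the fixed order M/B/T/E.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

#: Lineage column order used in tables.
LINEAGES: tuple[str, ...] = ("B", "T", "M", "E")

#: Order in which lineages appear inside clone-type labels.
LABEL_ORDER: tuple[str, ...] = ("M", "B", "T", "E")


def _all_clone_types() -> tuple[str, ...]:
    labels = []
    for k in range(1, 5):
        for combo in combinations(LABEL_ORDER, k):
            labels.append("/".join(combo))
    return tuple(labels)


#: The 15 canonical clone-type labels (all non-empty subsets of {M,B,T,E}).
CLONE_TYPES: tuple[str, ...] = _all_clone_types()


def clone_type_label(flags: dict[str, bool]) -> str:
    """Canonical label for a set of lineage-potential flags.

    Raises ``ValueError`` if no flag is set (an undetected clone has no
    type).
    """
    present = [lin for lin in LABEL_ORDER if flags.get(lin, False)]
    if not present:
        raise ValueError("clone with no detected lineage has no clone type")
    return "/".join(present)


def label_lineages(label: str) -> frozenset[str]:
    """Lineage set encoded by a clone-type label."""
    parts = label.split("/")
    if not parts or any(p not in LABEL_ORDER for p in parts):
        raise ValueError(f"not a clone-type label: {label!r}")
    return frozenset(parts)


def encode_seqs(seqs) -> np.ndarray:
    """Encode equal-length DNA strings as a (n, L) uint8 byte matrix."""
    seqs = list(seqs)
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences must be equal length")
    buf = "".join(seqs).encode("ascii")
    return np.frombuffer(buf, dtype=np.uint8).reshape(len(seqs), length)


def decode_seqs(mat: np.ndarray) -> list[str]:
    """Inverse of :func:`encode_seqs`."""
    return [row.tobytes().decode("ascii") for row in np.asarray(mat, dtype=np.uint8)]


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
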