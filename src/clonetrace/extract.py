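"""Barcode extraction and sequencing-error collapse.

Reads carrying the complete 27 bp barcode and 7 bp library ID are pulled
out of FASTQ by anchoring the constant amplicon context at fixed offsets;
reads failing the anchor or too short to contain the full tag are rejected
and tallied by reason.  Counts per raw barcode are then collapsed: a
low-count barcode within a small Hamming distance of a much larger one is
taken to be a sequencing-error derivative and merged into it, conserving
reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pysam

from .core import decode_seqs, encode_seqs
from .simulate import BarcodeLibrary

# Rejection reasons, in reporting order.
REASON_INCOMPLETE = "incomplete_tag"
REASON_FLANK = "flank_mismatch"
REASON_LIBRARY_ID = "library_id_mismatch"


@dataclass
class ExtractionResult:
    """Extracted tags plus per-reason rejection bookkeeping for one FASTQ."""

    tags: pd.DataFrame  # columns: read_id, barcode, library_id
    total_reads: int
    rejections: dict[str, int] = field(default_factory=dict)

    @property
    def kept(self) -> int:
        return len(self.tags)


def _constant_positions(library: BarcodeLibrary, anchor_len: int) -> tuple[np.ndarray, np.ndarray]:
    """(positions, expected bytes) of the constant context checked per read:
    the full left flank, the spacer, and the first ``anchor_len`` bases of
    the right flank."""
    layout = library.layout
    ref = (
        library.flank_left
        + "N" * (layout.barcode_end - layout.barcode_start)
        + library.spacer
        + library.library_id
        + library.flank_right
    )
    pos = list(range(0, layout.barcode_start))  # left flank
    pos += list(range(layout.barcode_end, layout.id_start))  # spacer
    pos += list(range(layout.id_end, min(layout.id_end + anchor_len, layout.read_length)))
    pos_arr = np.array(pos, dtype=int)
    exp = np.frombuffer(ref.encode("ascii"), dtype=np.uint8)[pos_arr]
    return pos_arr, exp


def extract_tags(
    fastq_path,
    library: BarcodeLibrary,
    max_flank_mismatch: int = 2,
    *,
    anchor_len: int = 10,
) -> ExtractionResult:
    """Extract (barcode, library ID) tags from one FASTQ file.

    A read yields a tag iff it is long enough to contain the full barcode
    and library-ID windows plus the right-flank anchor, and the constant
    context (left flank + spacer + ``anchor_len`` bases of right flank)
    matches with at most ``max_flank_mismatch`` mismatches.  'N' bases count
    as mismatches.  Malformed FASTQ raises with the failing record index.
    """
    layout = library.layout
    pos, expected = _constant_positions(library, anchor_len)
    required_len = int(pos.max()) + 1 if len(pos) else layout.id_end

    names: list[str] = []
    seqs: list[str] = []
    n_total = 0
    n_short = 0
    with open(fastq_path, "rb") as raw:
        head = raw.read(1)
    if head and head != b"@":
        raise ValueError(
            f"malformed FASTQ record near record 1 in {fastq_path}: "
            "file does not start with '@'"
        )
    try:
        with pysam.FastxFile(str(fastq_path)) as fh:
            for rec in fh:
                n_total += 1
                seq = rec.sequence or ""
                if len(seq) < required_len:
                    n_short += 1
                    continue
                names.append(rec.name)
                seqs.append(seq[:required_len].upper())
    except OSError:
        raise
    except Exception as exc:  # pysam signals malformed records generically
        raise ValueError(
            f"malformed FASTQ record near record {n_total + 1} in {fastq_path}: {exc}"
        ) from exc

    if not seqs:
        tags = pd.DataFrame(columns=["read_id", "barcode", "library_id"])
        return ExtractionResult(
            tags, n_total, {REASON_INCOMPLETE: n_short, REASON_FLANK: 0}
        )

    mat = encode_seqs(seqs)
    mism = (mat[:, pos] != expected[None, :]).sum(axis=1)
    ok = mism <= max_flank_mismatch
    n_flank = int((~ok).sum())
    kept = mat[ok]
    barcode = decode_seqs(kept[:, layout.barcode_start : layout.barcode_end])
    lib_id = decode_seqs(kept[:, layout.id_start : layout.id_end])
    tags = pd.DataFrame(
        {
            "read_id": np.asarray(names, dtype=object)[ok],
            "barcode": barcode,
            "library_id": lib_id,
        }
    )
    return ExtractionResult(
        tags, n_total, {REASON_INCOMPLETE: n_short, REASON_FLANK: n_flank}
    )


def filter_library_id(
    tags: pd.DataFrame, library: BarcodeLibrary, max_id_mismatch: int = 1
) -> pd.DataFrame:
    """Keep tags whose library ID is within Hamming ``max_id_mismatch`` of
    the library's ID."""
    if max_id_mismatch > len(library.library_id):
        raise ValueError("max_id_mismatch exceeds library ID length")
    if tags.empty:
        return tags
    mat = encode_seqs(tags["library_id"].tolist())
    exp = np.frombuffer(library.library_id.encode("ascii"), dtype=np.uint8)
    d = (mat != exp[None, :]).sum(axis=1)
    return tags.loc[d <= max_id_mismatch].reset_index(drop=True)


def collapse_errors(
    raw_counts: Mapping[str, int] | pd.Series,
    max_distance: int = 2,
    ratio_threshold: float = 1 / 8,
) -> dict[str, int]:
    """Merge sequencing-error-derived barcodes into their parent clones.

    Greedy pass over barcodes in descending count order (ties broken
    lexicographically): a barcode within Hamming ``max_distance`` of an
    already-accepted parent, with count strictly below ``ratio_threshold``
    times the parent's count, is merged into the nearest such parent (ties:
    larger parent count, then lexicographically smaller sequence);
    otherwise it is accepted as its own clone.  The pass repeats until a
    fixpoint, which makes the operation idempotent; total reads are
    conserved exactly.
    """
    if max_distance < 1:
        raise ValueError("max_distance must be >= 1")
    if not 0.0 < ratio_threshold < 1.0:
        raise ValueError("ratio_threshold must be in (0, 1)")
    counts = {str(k): int(v) for k, v in dict(raw_counts).items()}
    if any(v <= 0 for v in counts.values()):
        raise ValueError("counts must be positive")
    while True:
        new = _collapse_pass(counts, max_distance, ratio_threshold)
        if new == counts:
            return new
        counts = new


def _collapse_pass(
    counts: dict[str, int], max_distance: int, ratio_threshold: float
) -> dict[str, int]:
    if len(counts) <= 1:
        return dict(counts)
    order = sorted(counts, key=lambda s: (-counts[s], s))
    length = len(order[0])
    if any(len(s) != length for s in order):
        raise ValueError("all barcodes must have equal length")
    mats = encode_seqs(order)
    n = len(order)
    accepted_idx: list[int] = []
    accepted_mat = np.empty((n, length), dtype=np.uint8)
    out: dict[str, int] = {}
    for i, seq in enumerate(order):
        c = counts[seq]
        parent = None
        if accepted_idx:
            k = len(accepted_idx)
            d = (accepted_mat[:k] != mats[i][None, :]).sum(axis=1)
            cand = np.flatnonzero(d <= max_distance)
            if cand.size:
                eligible = [
                    j for j in cand
                    if c < ratio_threshold * counts[order[accepted_idx[j]]]
                ]
                if eligible:
                    parent = min(
                        eligible,
                        key=lambda j: (
                            int(d[j]),
                            -counts[order[accepted_idx[j]]],
                            order[accepted_idx[j]],
                        ),
                    )
        if parent is None:
            accepted_mat[len(accepted_idx)] = mats[i]
            accepted_idx.append(i)
            out[seq] = out.get(seq, 0) + c
        else:
            pseq = order[accepted_idx[parent]]
            out[pseq] = out.get(pseq, 0) + c
    return out


def build_count_table(
    manifest: pd.DataFrame,
    library: BarcodeLibrary,
    *,
    max_flank_mismatch: int = 2,
    max_id_mismatch: int = 1,
    max_distance: int = 2,
    ratio_threshold: float = 1 / 8,
    collapse: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Run extraction + collapse for every sample in a FASTQ manifest.

    ``manifest`` needs columns ``fastq, mouse, lineage``.  Returns the
    count table (mouse, lineage, barcode, reads) and a provenance dict with
    per-sample totals, rejection counts and the parameters used.  Samples
    whose FASTQ yields no tags are still recorded in the provenance (with
    zero kept reads) but contribute no count rows.
    """
    required = {"fastq", "mouse", "lineage"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    rows = []
    samples = []
    for rec in manifest.itertuples(index=False):
        path = Path(rec.fastq)
        if not path.exists():
            raise FileNotFoundError(f"FASTQ listed in manifest not found: {path}")
        res = extract_tags(path, library, max_flank_mismatch=max_flank_mismatch)
        tags = filter_library_id(res.tags, library, max_id_mismatch=max_id_mismatch)
        n_bad_id = res.kept - len(tags)
        counts = tags["barcode"].value_counts().to_dict()
        if collapse and counts:
            counts = collapse_errors(
                counts, max_distance=max_distance, ratio_threshold=ratio_threshold
            )
        for bc, c in counts.items():
            rows.append(
                {"mouse": rec.mouse, "lineage": rec.lineage, "barcode": bc, "reads": int(c)}
            )
        samples.append(
            {
                "mouse": rec.mouse,
                "lineage": rec.lineage,
                "fastq": str(path),
                "total_reads": res.total_reads,
                "kept_reads": int(len(tags)),
                REASON_INCOMPLETE: res.rejections.get(REASON_INCOMPLETE, 0),
                REASON_FLANK: res.rejections.get(REASON_FLANK, 0),
                REASON_LIBRARY_ID: n_bad_id,
            }
        )
    table = pd.DataFrame(rows, columns=["mouse", "lineage", "barcode", "reads"])
    table = table.sort_values(["mouse", "lineage", "reads", "barcode"],
                              ascending=[True, True, False, True]).reset_index(drop=True)
    provenance = {
        "samples": samples,
        "parameters": {
            "max_flank_mismatch": max_flank_mismatch,
            "max_id_mismatch": max_id_mismatch,
            "max_distance": max_distance,
            "ratio_threshold": ratio_threshold,
            "collapse": collapse,
        },
    }
    return table, provenance
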