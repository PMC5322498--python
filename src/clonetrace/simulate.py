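"""Synthetic barcoded-transplant experiments.

Emulates the study design that the downstream analysis assumes: donor HSCs
are transduced with a lentiviral barcode library (27 bp barcode + 7 bp
library ID inside a 238 bp amplicon), transplanted into irradiated
recipients together with unbarcoded competitor cells, and their progeny in
four lineages (B, T, myeloid, erythroid) are deep-sequenced long after
transplant.  The generator produces, per experiment:

* a truth table (one row per clone: barcode, lineage-potential flags and
  true per-lineage output weights),
* per-(mouse, lineage) FASTQ files with substitution errors, together with
  the error-free expected count table,
* a sample sheet carrying the design parameters the quantification stage
  needs (cell dose, transduction fraction, per-lineage GFP+ donor fraction).

The reference configurations encode the printed study design: 1,000 young
cells at 31% transduction and 6,900 aged cells at 29% transduction, five
mice per group, with clone-type distributions whose per-type means and
pooled lineage contributions match the published young/aged values.

A companion generator emulates the molecular arm of the study: single-cell
qPCR Ct matrices for young / mid-aged / aged / iPS-HSC groups with
reference-gene anchoring, and bulk young/aged expression matrices for the
panel-selection filters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CLONE_TYPES, LINEAGES, decode_seqs, encode_seqs, label_lineages

# ---------------------------------------------------------------------------
# Amplicon layout (fixed constants; offsets are 0-based half-open)
# ---------------------------------------------------------------------------

AMPLICON_LENGTH = 238
FLANK_LEFT = "ACTGACGTCAGTACGATCGA"  # 20 bp vector context upstream of barcode
SPACER = "GATCCTAG"  # 8 bp between barcode and library ID
BARCODE_LENGTH = 27
LIBRARY_ID_LENGTH = 7
DEFAULT_LIBRARY_ID = "GTACGAT"

# 176 bp of constant context downstream of the library ID, padding to 238 bp
FLANK_RIGHT = (
    "TCGATCAGGCATCGTACGGATTCACGGTACGATCAGCTAGGATCCGTACGATCGGA"
    "TCACGATCGGTACCAGGATCGATCCGGTACGAGCTACGATCGGATCAGCATCGTAC"
    "GGATCCGATCAGGCTACGGATCGTACCAGGATCGACTCGGTACGATCCGGATCAGG"
    "TACGATCA"
)
assert (
    len(FLANK_LEFT) + BARCODE_LENGTH + len(SPACER) + LIBRARY_ID_LENGTH + len(FLANK_RIGHT)
    == AMPLICON_LENGTH
)


@dataclass(frozen=True)
class AmpliconLayout:
    """0-based half-open coordinates of the tag windows within a read."""

    barcode_start: int = len(FLANK_LEFT)
    barcode_end: int = len(FLANK_LEFT) + BARCODE_LENGTH
    id_start: int = len(FLANK_LEFT) + BARCODE_LENGTH + len(SPACER)
    id_end: int = len(FLANK_LEFT) + BARCODE_LENGTH + len(SPACER) + LIBRARY_ID_LENGTH
    read_length: int = AMPLICON_LENGTH


@dataclass(frozen=True)
class BarcodeLibrary:
    """A set of known 27 bp barcodes sharing one 7 bp library ID."""

    barcodes: tuple[str, ...]
    library_id: str = DEFAULT_LIBRARY_ID
    flank_left: str = FLANK_LEFT
    spacer: str = SPACER
    flank_right: str = FLANK_RIGHT

    def __post_init__(self) -> None:
        if any(len(b) != BARCODE_LENGTH for b in self.barcodes):
            raise ValueError(f"all barcodes must be {BARCODE_LENGTH} bp")
        if len(self.library_id) != LIBRARY_ID_LENGTH:
            raise ValueError(f"library ID must be {LIBRARY_ID_LENGTH} bp")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes must be unique within the library")

    @property
    def layout(self) -> AmpliconLayout:
        fl = len(self.flank_left)
        return AmpliconLayout(
            barcode_start=fl,
            barcode_end=fl + BARCODE_LENGTH,
            id_start=fl + BARCODE_LENGTH + len(self.spacer),
            id_end=fl + BARCODE_LENGTH + len(self.spacer) + LIBRARY_ID_LENGTH,
            read_length=fl
            + BARCODE_LENGTH
            + len(self.spacer)
            + LIBRARY_ID_LENGTH
            + len(self.flank_right),
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame({"barcode": self.barcodes, "library_id": self.library_id}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "BarcodeLibrary":
        df = pd.read_csv(path, sep="\t")
        return cls(tuple(df["barcode"]), library_id=str(df["library_id"].iloc[0]))


def generate_barcode_library(
    n: int,
    min_pairwise_distance: int = 3,
    seed: int = 0,
    *,
    library_id: str = DEFAULT_LIBRARY_ID,
    max_attempts_per_barcode: int = 200,
) -> BarcodeLibrary:
    """Draw ``n`` random 27 bp barcodes with pairwise Hamming distance
    ``>= min_pairwise_distance``.

    Rejection sampling against the accepted set; raises ``ValueError`` when
    the request is infeasible (distance exceeds the barcode length) or the
    attempt budget is exhausted, signalling infeasible parameters.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if min_pairwise_distance < 0:
        raise ValueError("min_pairwise_distance must be >= 0")
    if min_pairwise_distance > BARCODE_LENGTH:
        raise ValueError(
            f"min pairwise distance {min_pairwise_distance} exceeds the "
            f"maximum Hamming distance ({BARCODE_LENGTH}) on {BARCODE_LENGTH} bp barcodes"
        )
    rng = np.random.default_rng(seed)
    accepted = np.empty((n, BARCODE_LENGTH), dtype=np.uint8)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    count = 0
    attempts = 0
    budget = max_attempts_per_barcode * n
    while count < n:
        if attempts >= budget:
            raise ValueError(
                f"could not place {n} barcodes at pairwise distance "
                f">= {min_pairwise_distance} within {budget} attempts"
            )
        cand = bases[rng.integers(0, 4, size=BARCODE_LENGTH)]
        attempts += 1
        if count and min_pairwise_distance > 0:
            d = (accepted[:count] != cand[None, :]).sum(axis=1)
            if int(d.min()) < min_pairwise_distance:
                continue
        elif count and min_pairwise_distance == 0:
            # uniqueness is still required
            if ((accepted[:count] != cand[None, :]).sum(axis=1) == 0).any():
                continue
        accepted[count] = cand
        count += 1
    return BarcodeLibrary(tuple(decode_seqs(accepted)), library_id=library_id)


# ---------------------------------------------------------------------------
# Transplant configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Design parameters for one transplant group.

    ``clone_type_distribution`` maps each of the 15 clone-type labels to the
    probability that a barcoded clone has that lineage-potential
    combination.  ``gfp_fraction_per_lineage`` is the GFP+ (barcoded)
    fraction among donor-derived cells of each lineage; it controls how many
    of a sample's reads carry a barcode (the remainder is the unbarcoded
    competitor sink).  ``sigma_log`` is the natural-log s.d. of the
    log-normal clone output weights.
    """

    n_cells_transplanted: int
    transduction_fraction: float
    n_mice: int
    clone_type_distribution: Mapping[str, float]
    read_depth: int = 100_000
    error_rate: float = 0.0
    clone_size_scale: Mapping[str, float] = field(
        default_factory=lambda: {lin: 1.0 for lin in LINEAGES}
    )
    gfp_fraction_per_lineage: Mapping[str, float] = field(
        default_factory=lambda: {lin: 0.2 for lin in LINEAGES}
    )
    sigma_log: float = 0.1
    group: str = "group"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells_transplanted < 1:
            raise ValueError("n_cells_transplanted must be >= 1")
        if not 0.0 <= self.transduction_fraction <= 1.0:
            raise ValueError("transduction_fraction must be in [0, 1]")
        if self.n_mice < 1:
            raise ValueError("n_mice must be >= 1")
        if self.read_depth < 0:
            raise ValueError("read_depth must be >= 0")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        missing = set(CLONE_TYPES) - set(self.clone_type_distribution)
        if missing:
            raise ValueError(
                f"clone_type_distribution must cover all 15 clone types; "
                f"missing {sorted(missing)}"
            )
        total = float(sum(self.clone_type_distribution.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"clone_type_distribution sums to {total}, not 1")
        for lin in LINEAGES:
            g = self.gfp_fraction_per_lineage.get(lin)
            if g is None:
                raise ValueError(f"gfp_fraction_per_lineage missing lineage {lin}")
            if not 0.0 < g <= 1.0:
                raise ValueError(f"gfp fraction for {lin} must be in (0, 1]")

    @property
    def expected_gfp_cells(self) -> int:
        """Expected number of barcoded (GFP+) cells transplanted."""
        return int(round(self.n_cells_transplanted * self.transduction_fraction))

    def mouse_ids(self) -> list[str]:
        return [f"{self.group}_{i + 1}" for i in range(self.n_mice)]


# Reference clone-type distributions.  Constructed once to satisfy the
# published constraints jointly: per-type means M 6/13%, M/E 10/19%,
# M/B/T/E 13/1% (young/aged); pooled lineage contributions myeloid 38/60%
# and T 45/3%; B and erythroid contributions similar across age (51/51%,
# 63/67%).
YOUNG_CLONE_TYPE_DISTRIBUTION: dict[str, float] = {
    "M": 0.06, "B": 0.08, "T": 0.10, "E": 0.17,
    "M/B": 0.02, "M/T": 0.01, "M/E": 0.10, "B/T": 0.08, "B/E": 0.09, "T/E": 0.04,
    "M/B/T": 0.02, "M/B/E": 0.03, "M/T/E": 0.01, "B/T/E": 0.06,
    "M/B/T/E": 0.13,
}

AGED_CLONE_TYPE_DISTRIBUTION: dict[str, float] = {
    "M": 0.13, "B": 0.12, "T": 0.005, "E": 0.165,
    "M/B": 0.065, "M/T": 0.0, "M/E": 0.19, "B/T": 0.005, "B/E": 0.10, "T/E": 0.0,
    "M/B/T": 0.005, "M/B/E": 0.20, "M/T/E": 0.0, "B/T/E": 0.005,
    "M/B/T/E": 0.01,
}

# GFP+ donor fractions per lineage.  Young uniform 0.20; aged values derived
# from the reference design so that young:aged mean clone-size ratios come
# out at the published 20- (B), 29- (E) and 39-fold (M), and ~1-fold for T.
YOUNG_GFP_FRACTIONS: dict[str, float] = {"B": 0.20, "T": 0.20, "M": 0.20, "E": 0.20}
AGED_GFP_FRACTIONS: dict[str, float] = {"B": 0.620, "T": 0.465, "M": 0.765, "E": 0.845}


def young_reference_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Study design for the young donor group (1,000 cells, 31% transduction,
    five recipients)."""
    base = dict(
        n_cells_transplanted=1_000,
        transduction_fraction=0.31,
        n_mice=5,
        clone_type_distribution=YOUNG_CLONE_TYPE_DISTRIBUTION,
        gfp_fraction_per_lineage=YOUNG_GFP_FRACTIONS,
        read_depth=100_000,
        error_rate=0.005,
        group="young",
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def aged_reference_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Study design for the aged donor group (6,900 cells, 29% transduction,
    five recipients)."""
    base = dict(
        n_cells_transplanted=6_900,
        transduction_fraction=0.29,
        n_mice=5,
        clone_type_distribution=AGED_CLONE_TYPE_DISTRIBUTION,
        gfp_fraction_per_lineage=AGED_GFP_FRACTIONS,
        read_depth=100_000,
        error_rate=0.005,
        group="aged",
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


# ---------------------------------------------------------------------------
# Transplant and read simulation
# ---------------------------------------------------------------------------


def simulate_transplant(
    config: SimulationConfig,
    library: BarcodeLibrary,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw the clone pool of each recipient mouse.

    Per mouse, the number of barcoded clones is Binomial(cells transplanted,
    transduction fraction); each clone receives a barcode drawn without
    replacement from the library (barcode namespaces are per mouse, so the
    same sequence may recur in another mouse), a clone type drawn from the
    configured distribution, and independent log-normal output weights in
    each lineage for which it has potential.

    Returns the truth table with columns ``mouse, barcode, clone_type,
    B, T, M, E`` (0/1 flags) and ``weight_B .. weight_E``.
    """
    if not library.barcodes:
        raise ValueError("barcode library is empty")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    type_labels = list(CLONE_TYPES)
    probs = np.array([config.clone_type_distribution[t] for t in type_labels], dtype=float)
    probs = probs / probs.sum()
    rows: list[pd.DataFrame] = []
    for mouse in config.mouse_ids():
        n_clones = int(
            rng.binomial(config.n_cells_transplanted, config.transduction_fraction)
        )
        if n_clones > len(library.barcodes):
            raise ValueError(
                f"library too small: {n_clones} clones drawn for {mouse} but "
                f"only {len(library.barcodes)} barcodes available"
            )
        if n_clones == 0:
            continue
        barcodes = rng.choice(len(library.barcodes), size=n_clones, replace=False)
        types = rng.choice(len(type_labels), size=n_clones, p=probs)
        df = pd.DataFrame(
            {
                "mouse": mouse,
                "barcode": [library.barcodes[i] for i in barcodes],
                "clone_type": [type_labels[i] for i in types],
            }
        )
        for lin in LINEAGES:
            has = np.array(
                [lin in label_lineages(type_labels[i]) for i in types], dtype=bool
            )
            scale = float(config.clone_size_scale.get(lin, 1.0))
            s = config.sigma_log
            # mean-1 log-normal times the per-lineage scale
            w = scale * np.exp(rng.normal(-0.5 * s * s, s, size=n_clones))
            df[lin] = has.astype(int)
            df[f"weight_{lin}"] = np.where(has, w, 0.0)
        rows.append(df)
    if not rows:
        return pd.DataFrame(
            columns=["mouse", "barcode", "clone_type"]
            + list(LINEAGES)
            + [f"weight_{lin}" for lin in LINEAGES]
        )
    return pd.concat(rows, ignore_index=True)


_QUALITY_CHAR = "I"


def _mutate_reads(seq_mat: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Apply i.i.d. substitution errors to byte-encoded reads in place."""
    if error_rate <= 0 or seq_mat.size == 0:
        return seq_mat
    mask = rng.random(seq_mat.shape) < error_rate
    n_err = int(mask.sum())
    if n_err == 0:
        return seq_mat
    # substitute with one of the three other bases, uniformly
    code = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        code[b] = i
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    orig = code[seq_mat[mask]]
    shift = rng.integers(1, 4, size=n_err)
    seq_mat[mask] = bases[(orig + shift) % 4]
    return seq_mat


def simulate_reads(
    truth: pd.DataFrame,
    config: SimulationConfig,
    library: BarcodeLibrary,
    outdir,
    rng: np.random.Generator | None = None,
) -> dict[str, pd.DataFrame]:
    """Write per-(mouse, lineage) FASTQ files and the expected count table.

    Per sample, ``read_depth`` reads are allocated by a single multinomial
    draw with probability ``(w_i / sum w) * gfp_fraction`` for clone ``i``
    and ``1 - gfp_fraction`` for the unbarcoded competitor class; competitor
    reads are counted but not emitted.  Each emitted read is the constant
    amplicon carrying the clone's barcode, with i.i.d. substitution errors
    at ``error_rate`` and constant qualities.

    Returns a dict with ``manifest`` (fastq, mouse, lineage),
    ``expected_counts`` (mouse, lineage, barcode, reads: the error-free
    allocation) and ``sample_sheet``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    for lin in LINEAGES:
        if lin not in config.gfp_fraction_per_lineage:
            raise ValueError(f"lineage {lin} missing from gfp_fraction_per_lineage")

    manifest_rows = []
    count_rows = []
    sheet_rows = []
    amplicon = library.flank_left + "{bc}" + library.spacer + library.library_id + library.flank_right
    qual = _QUALITY_CHAR * library.layout.read_length
    mice = config.mouse_ids()
    for mouse in mice:
        clones = truth[truth["mouse"] == mouse]
        for lin in LINEAGES:
            gfp = float(config.gfp_fraction_per_lineage[lin])
            sheet_rows.append(
                {
                    "mouse": mouse,
                    "group": config.group,
                    "lineage": lin,
                    "gfp_fraction": gfp,
                    "n_cells_transplanted": config.n_cells_transplanted,
                    "transduction_fraction": config.transduction_fraction,
                }
            )
            weights = clones[f"weight_{lin}"].to_numpy(dtype=float)
            active = weights > 0
            barcodes = clones["barcode"].to_numpy()[active]
            w = weights[active]
            if w.size:
                p = np.concatenate([w / w.sum() * gfp, [1.0 - gfp]])
            else:
                p = np.array([1.0])
            p = p / p.sum()
            alloc = rng.multinomial(config.read_depth, p)
            counts = alloc[:-1] if w.size else np.empty(0, dtype=int)
            fastq_path = outdir / f"{mouse}_{lin}.fastq"
            _write_sample_fastq(
                fastq_path, mouse, lin, barcodes, counts, amplicon, qual,
                config.error_rate, rng,
            )
            manifest_rows.append(
                {"fastq": str(fastq_path), "mouse": mouse, "lineage": lin}
            )
            for bc, c in zip(barcodes, counts):
                if c > 0:
                    count_rows.append(
                        {"mouse": mouse, "lineage": lin, "barcode": bc, "reads": int(c)}
                    )
    expected = pd.DataFrame(count_rows, columns=["mouse", "lineage", "barcode", "reads"])
    manifest = pd.DataFrame(manifest_rows)
    sheet = pd.DataFrame(sheet_rows)
    return {"manifest": manifest, "expected_counts": expected, "sample_sheet": sheet}


def _write_sample_fastq(
    path: Path,
    mouse: str,
    lineage: str,
    barcodes: Sequence[str],
    counts: np.ndarray,
    amplicon_template: str,
    qual: str,
    error_rate: float,
    rng: np.random.Generator,
) -> None:
    n_reads = int(counts.sum()) if len(counts) else 0
    if n_reads == 0:
        path.write_text("")
        return
    templates = encode_seqs(
        [amplicon_template.format(bc=bc) for bc in barcodes]
    )
    clone_idx = np.repeat(np.arange(len(barcodes)), counts)
    reads = templates[clone_idx].copy()
    _mutate_reads(reads, error_rate, rng)
    seqs = decode_seqs(reads)
    with open(path, "w") as fh:
        fh.write(
            "".join(
                f"@{mouse}:{lineage}:{i}\n{seq}\n+\n{qual}\n"
                for i, seq in enumerate(seqs)
            )
        )


def simulate_experiment(
    config: SimulationConfig,
    library: BarcodeLibrary | None = None,
    outdir=None,
) -> dict:
    """Convenience wrapper: library (if needed) + transplant + reads.

    Returns a dict with ``truth``, ``manifest``, ``expected_counts``,
    ``sample_sheet`` and ``library``.  All randomness flows from a single
    generator seeded with ``config.seed``, in documented order: library,
    transplant, then reads sample by sample (mice in order, lineages in
    B/T/M/E order).
    """
    rng = np.random.default_rng(config.seed)
    if library is None:
        # size the library for the largest plausible clone count per mouse
        mean = config.n_cells_transplanted * config.transduction_fraction
        sd = math.sqrt(mean * (1 - config.transduction_fraction))
        n = int(mean + 6 * sd) + 10
        library = generate_barcode_library(
            n, min_pairwise_distance=3, seed=int(rng.integers(0, 2**31 - 1))
        )
    truth = simulate_transplant(config, library, rng=rng)
    if outdir is None:
        raise ValueError("outdir is required to write FASTQ files")
    out = simulate_reads(truth, config, library, outdir, rng=rng)
    out["truth"] = truth
    out["library"] = library
    return out


def simulate_study(outdir, seed: int = 0, **overrides) -> dict:
    """Simulate the full reference study: five young and five aged mice.

    ``overrides`` are applied to both group configs (e.g. ``error_rate=0``).
    Returns combined ``truth``, ``manifest``, ``expected_counts``,
    ``sample_sheet``, plus ``groups`` (mouse -> group) and the per-group
    configs.
    """
    outdir = Path(outdir)
    young = young_reference_config(seed=seed, **overrides)
    aged = aged_reference_config(seed=seed + 1, **overrides)
    shared_library = generate_barcode_library(
        2600, min_pairwise_distance=3, seed=seed + 2
    )
    res_y = simulate_experiment(young, library=shared_library, outdir=outdir / "young")
    res_a = simulate_experiment(aged, library=shared_library, outdir=outdir / "aged")
    out = {
        "truth": pd.concat([res_y["truth"], res_a["truth"]], ignore_index=True),
        "manifest": pd.concat([res_y["manifest"], res_a["manifest"]], ignore_index=True),
        "expected_counts": pd.concat(
            [res_y["expected_counts"], res_a["expected_counts"]], ignore_index=True
        ),
        "sample_sheet": pd.concat(
            [res_y["sample_sheet"], res_a["sample_sheet"]], ignore_index=True
        ),
        "library": shared_library,
        "configs": {"young": young, "aged": aged},
    }
    out["groups"] = {
        m: ("young" if m.startswith("young") else "aged")
        for m in out["sample_sheet"]["mouse"].unique()
    }
    return out


# ---------------------------------------------------------------------------
# Single-cell qPCR and bulk expression emulation
# ---------------------------------------------------------------------------

REFERENCE_GENES = ("Actb", "Hprt", "Gapdh")

#: Synthetic stand-in for the study's 45-gene assay panel (42 age-responsive
#: genes + 3 reference genes).  The real panel membership is not public in
#: machine-readable form; these placeholder symbols configure the synthetic
#: single-cell workflow only.
SYNTHETIC_AGE_PANEL: tuple[str, ...] = REFERENCE_GENES + tuple(
    f"Age{i:02d}" for i in range(1, 43)
)


def default_age_effects(magnitude: float = 1.5) -> dict[str, float]:
    """Default per-gene aged-vs-young Ct shifts for the synthetic panel.

    Alternating sign: half the age genes lose expression with age (positive
    Ct shift), half gain it.  1.5 cycles is ~2.8-fold, comfortably above the
    1.5-fold panel-selection filter.
    """
    genes = [g for g in SYNTHETIC_AGE_PANEL if g not in REFERENCE_GENES]
    return {g: (magnitude if i % 2 == 0 else -magnitude) for i, g in enumerate(genes)}


@dataclass
class CtMatrix:
    """Single-cell qPCR Ct values (cells x genes) with group labels.

    Failed reactions are ``NaN`` in memory and "NA" on disk.  ``lod_ct`` is
    the limit of detection (the run's cycle count).
    """

    values: pd.DataFrame
    groups: pd.Series
    reference_genes: tuple[str, ...] = REFERENCE_GENES
    lod_ct: float = 30.0

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "group", self.groups)
        out.to_csv(path, na_rep="NA")

    @classmethod
    def from_csv(cls, path, reference_genes=REFERENCE_GENES, lod_ct: float = 30.0) -> "CtMatrix":
        df = pd.read_csv(path, index_col=0)
        groups = df.pop("group")
        return cls(df, groups, tuple(reference_genes), lod_ct)


CT_GROUPS = ("young", "mid-aged", "aged", "iPS-HSC")


def simulate_ct_matrix(
    n_cells_per_group: Mapping[str, int],
    panel: Sequence[str] = SYNTHETIC_AGE_PANEL,
    effect_sizes: Mapping[str, float] | None = None,
    dropout_rate: float = 0.1,
    seed: int = 0,
    *,
    lod_ct: float = 30.0,
    reference_genes: Sequence[str] = REFERENCE_GENES,
    noise_sd: float = 1.0,
    cell_offset_sd: float = 0.8,
    mid_aged_factor: float = 0.6,
) -> CtMatrix:
    """Generate single-cell Ct matrices for the four assay groups.

    Ct values are Gaussian around per-gene baselines; the aged group is
    shifted gene-wise by ``effect_sizes`` (positive shift = higher Ct =
    lower expression), the mid-aged group by ``mid_aged_factor`` times the
    effect, and iPS-HSC cells are drawn from the young distribution.  A
    per-cell offset (cell size / lysis efficiency) shifts all genes of a
    cell equally and is what reference-gene centering removes downstream.
    Failed reactions appear as NaN at ``dropout_rate``; values are clipped
    into (0, lod_ct].
    """
    panel = list(panel)
    refs = [g for g in reference_genes]
    missing_refs = set(refs) - set(panel)
    if missing_refs:
        raise ValueError(f"panel must include the reference genes; missing {sorted(missing_refs)}")
    if effect_sizes is None:
        effect_sizes = default_age_effects()
    unknown = set(effect_sizes) - set(panel)
    if unknown:
        raise ValueError(f"effect size specified for genes absent from panel: {sorted(unknown)}")
    if not 0.0 <= dropout_rate <= 1.0:
        raise ValueError("dropout_rate must be in [0, 1]")

    rng = np.random.default_rng(seed)
    baseline = pd.Series(rng.uniform(14.0, 24.0, size=len(panel)), index=panel)
    for g in refs:
        baseline[g] = rng.uniform(14.0, 16.0)
    shift_scale = {"young": 0.0, "iPS-HSC": 0.0, "mid-aged": mid_aged_factor, "aged": 1.0}

    frames = []
    group_labels = []
    cell_ids = []
    for group in CT_GROUPS:
        n = int(n_cells_per_group.get(group, 0))
        if n == 0:
            continue
        shift = np.array(
            [shift_scale[group] * float(effect_sizes.get(g, 0.0)) for g in panel]
        )
        offsets = rng.normal(0.0, cell_offset_sd, size=n)
        vals = (
            baseline.to_numpy()[None, :]
            + shift[None, :]
            + offsets[:, None]
            + rng.normal(0.0, noise_sd, size=(n, len(panel)))
        )
        vals = np.clip(vals, 1e-3, lod_ct)
        drop = rng.random((n, len(panel))) < dropout_rate
        vals = np.where(drop, np.nan, vals)
        frames.append(pd.DataFrame(vals, columns=panel))
        group_labels.extend([group] * n)
        cell_ids.extend([f"{group}_{i + 1}" for i in range(n)])
    if frames:
        values = pd.concat(frames, ignore_index=True)
        values.index = pd.Index(cell_ids, name="cell")
    else:
        values = pd.DataFrame(columns=panel)
    groups = pd.Series(group_labels, index=values.index, name="group")
    return CtMatrix(values, groups, tuple(refs), lod_ct)


def simulate_bulk_expression(
    n_genes: int = 400,
    n_per_group: int = 6,
    n_regulated: int = 60,
    fold: float = 2.5,
    seed: int = 0,
    *,
    base_mean: float = 300.0,
    low_fraction: float = 0.2,
    cv: float = 0.15,
) -> dict:
    """Bulk young/aged expression matrices for panel selection.

    ``n_regulated`` genes (half up with age, half down) change by ``fold``;
    ``low_fraction`` of genes sit below the 50-intensity noise floor in all
    samples.  Returns dict with ``expr`` (genes x samples), ``labels``
    (sample -> young/aged) and the truth sets ``up``/``down``.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    n_low = int(low_fraction * n_genes)
    n_up = n_regulated // 2
    n_down = n_regulated - n_up
    base = rng.uniform(base_mean * 0.3, base_mean * 3.0, size=n_genes)
    base[:n_low] = rng.uniform(5.0, 40.0, size=n_low)  # below the floor everywhere
    up = genes[n_low : n_low + n_up]
    down = genes[n_low + n_up : n_low + n_up + n_down]
    aged_mult = np.ones(n_genes)
    aged_mult[n_low : n_low + n_up] = fold
    aged_mult[n_low + n_up : n_low + n_up + n_down] = 1.0 / fold
    cols = {}
    labels = {}
    for j in range(n_per_group):
        name = f"young_{j + 1}"
        cols[name] = base * rng.normal(1.0, cv, size=n_genes).clip(0.3)
        labels[name] = "young"
    for j in range(n_per_group):
        name = f"aged_{j + 1}"
        cols[name] = base * aged_mult * rng.normal(1.0, cv, size=n_genes).clip(0.3)
        labels[name] = "aged"
    expr = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    return {"expr": expr, "labels": pd.Series(labels), "up": list(up), "down": list(down)}
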