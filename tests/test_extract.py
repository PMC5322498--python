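"""Tag extraction, library-ID filtering and error collapse."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import clonetrace as ct
from clonetrace.core import hamming
from clonetrace.extract import (
    REASON_FLANK,
    REASON_INCOMPLETE,
    collapse_errors,
    extract_tags,
    filter_library_id,
)

def write_fastq(path, seqs):
    with open(path, "w") as fh:
        for i, s in enumerate(seqs):
            fh.write(f"@r{i}\n{s}\n+\n{'I' * len(s)}\n")
    return path


def amplicon(lib, barcode, library_id=None):
    return (
        lib.flank_left + barcode + lib.spacer
        + (library_id or lib.library_id) + lib.flank_right
    )


# ---------------------------------------------------------------------------
# extract_tags
# ---------------------------------------------------------------------------


class TestExtractTags:
    def test_exact_construction_yields_tag(self, small_library, tmp_path):
        bc = small_library.barcodes[0]
        path = write_fastq(tmp_path / "x.fastq", [amplicon(small_library, bc)])
        res = extract_tags(path, small_library, max_flank_mismatch=0)
        assert res.kept == 1
        assert res.tags["barcode"].iloc[0] == bc
        assert res.tags["library_id"].iloc[0] == small_library.library_id

    def test_truncated_read_rejected_as_incomplete(self, small_library, tmp_path):
        bc = small_library.barcodes[0]
        full = amplicon(small_library, bc)
        # cut just before the library ID window: complete tag impossible
        trunc = full[: small_library.layout.id_start + 3]
        path = write_fastq(tmp_path / "t.fastq", [trunc])
        res = extract_tags(path, small_library)
        assert res.kept == 0
        assert res.rejections[REASON_INCOMPLETE] == 1

    def test_flank_mismatch_budget(self, small_library, tmp_path):
        bc = small_library.barcodes[0]
        read = amplicon(small_library, bc)
        # three substitutions inside the left flank
        broken = "GGG" + read[3:]  # left flank starts ACT: three mismatches
        path = write_fastq(tmp_path / "f.fastq", [read, broken])
        res2 = extract_tags(path, small_library, max_flank_mismatch=2)
        assert res2.kept + res2.rejections[REASON_FLANK] == 2
        assert res2.rejections[REASON_FLANK] >= 1
        res3 = extract_tags(path, small_library, max_flank_mismatch=3)
        assert res3.kept == 2

    def test_agrees_with_naive_matcher_on_noisy_reads(self, tmp_path):
        """Vectorised extraction equals a per-read brute-force matcher on
        10,000 simulated reads at 1% substitution error."""
        lib = ct.generate_barcode_library(20, 3, seed=21)
        cfg = ct.SimulationConfig(
            n_cells_transplanted=30, transduction_fraction=0.5, n_mice=1,
            clone_type_distribution=ct.YOUNG_CLONE_TYPE_DISTRIBUTION,
            read_depth=10_000, error_rate=0.01,
            gfp_fraction_per_lineage={lin: 1.0 for lin in ct.LINEAGES},
            seed=22,
        )
        res = ct.simulate_experiment(cfg, library=lib, outdir=tmp_path)
        fastq = res["manifest"]["fastq"].iloc[2]  # the myeloid sample
        got = extract_tags(fastq, lib, max_flank_mismatch=2, anchor_len=10)

        # independent oracle: explicit python string comparison per read
        layout = lib.layout
        const = (
            [(i, b) for i, b in enumerate(lib.flank_left)]
            + [(layout.barcode_end + i, b) for i, b in enumerate(lib.spacer)]
            + [(layout.id_end + i, b) for i, b in enumerate(lib.flank_right[:10])]
        )
        kept = []
        with open(fastq) as fh:
            lines = fh.read().splitlines()
        for seq in lines[1::4]:
            if len(seq) < layout.id_end + 10:
                continue
            mism = sum(1 for i, b in const if seq[i] != b)
            if mism <= 2:
                kept.append(
                    (seq[layout.barcode_start:layout.barcode_end],
                     seq[layout.id_start:layout.id_end])
                )
        assert got.kept == len(kept)
        assert sorted(zip(got.tags["barcode"], got.tags["library_id"])) == sorted(kept)

    def test_malformed_fastq_raises(self, small_library, tmp_path):
        path = tmp_path / "bad.fastq"
        path.write_text("this is not fastq\nat all\n")
        with pytest.raises(ValueError, match="malformed"):
            extract_tags(path, small_library)


class TestFilterLibraryId:
    def test_exact_id_kept_and_3_mismatch_dropped(self, small_library):
        good = small_library.library_id
        bad = ("AAA" + good[3:]) if good[:3] != "AAA" else ("TTT" + good[3:])
        tags = pd.DataFrame(
            {"read_id": ["a", "b"], "barcode": ["A" * 27] * 2,
             "library_id": [good, bad]}
        )
        out = filter_library_id(tags, small_library, max_id_mismatch=1)
        assert out["read_id"].tolist() == ["a"]

    def test_matches_brute_force_hamming_filter(self, small_library):
        rng = np.random.default_rng(31)
        ids = ["".join(rng.choice(list("ACGT"), 7)) for _ in range(500)]
        tags = pd.DataFrame(
            {"read_id": [str(i) for i in range(500)],
             "barcode": ["A" * 27] * 500, "library_id": ids}
        )
        for maxm in (0, 1, 2):
            out = filter_library_id(tags, small_library, max_id_mismatch=maxm)
            expect = [
                i for i, s in enumerate(ids)
                if hamming(s, small_library.library_id) <= maxm
            ]
            assert out["read_id"].astype(int).tolist() == expect


# ---------------------------------------------------------------------------
# collapse_errors
# ---------------------------------------------------------------------------


def oracle_collapse(counts, max_distance, ratio):
    """Brute-force reference: the greedy merge rule evaluated with plain
    python string operations, repeated until stable."""
    counts = dict(counts)
    while True:
        order = sorted(counts, key=lambda s: (-counts[s], s))
        accepted = []
        out = {}
        for seq in order:
            c = counts[seq]
            cands = [
                p for p in accepted
                if hamming(p, seq) <= max_distance and c < ratio * counts[p]
            ]
            if cands:
                parent = min(
                    cands, key=lambda p: (hamming(p, seq), -counts[p], p)
                )
                out[parent] += c
            else:
                accepted.append(seq)
                out[seq] = c
        if out == counts:
            return out
        counts = out


BC = "AAAAAAAAAAAAAAAAAAAAAAAAAAA"  # 27 x A


def mutate(seq, positions, base="C"):
    s = list(seq)
    for p in positions:
        s[p] = base
    return "".join(s)


class TestCollapseErrors:
    def test_satellite_merged_into_parent(self):
        sat = mutate(BC, [5])
        out = collapse_errors({BC: 1000, sat: 3}, max_distance=2, ratio_threshold=1 / 8)
        assert out == {BC: 1003}

    def test_distant_equal_barcodes_untouched(self):
        other = mutate(BC, [0, 5, 10, 15, 20])
        out = collapse_errors({BC: 1000, other: 1000}, max_distance=2,
                              ratio_threshold=1 / 8)
        assert out == {BC: 1000, other: 1000}

    def test_single_barcode_identity(self):
        assert collapse_errors({BC: 7}) == {BC: 7}

    def test_total_reads_conserved_and_idempotent_random(self):
        rng = np.random.default_rng(17)
        for trial in range(30):
            n = rng.integers(2, 11)
            seqs = set()
            while len(seqs) < n:
                seqs.add("".join(rng.choice(list("ACGT"), 27)))
            # add near-duplicates to exercise merging
            seqs = list(seqs)
            if len(seqs) < 10:
                seqs.append(mutate(seqs[0], [int(rng.integers(27))], "G"))
            counts = {s: int(rng.integers(1, 2000)) for s in set(seqs)}
            out = collapse_errors(counts, 2, 1 / 8)
            assert sum(out.values()) == sum(counts.values())
            assert collapse_errors(out, 2, 1 / 8) == out

    @pytest.mark.parametrize("max_distance", [1, 2, 3])
    @pytest.mark.parametrize("ratio", [1 / 8, 1 / 4, 1 / 2])
    def test_equals_exhaustive_oracle(self, max_distance, ratio):
        """On <=10-barcode tables the greedy collapse equals the
        brute-force pairwise-merge oracle for every parameter setting."""
        rng = np.random.default_rng(int(max_distance * 100 + ratio * 1000))
        for trial in range(40):
            base = "".join(rng.choice(list("ACGT"), 27))
            table = {base: int(rng.integers(50, 3000))}
            while len(table) < rng.integers(2, 11):
                if rng.random() < 0.6:
                    k = int(rng.integers(1, 4))
                    pos = rng.choice(27, size=k, replace=False)
                    seq = mutate(base, pos, rng.choice(list("ACGT")))
                else:
                    seq = "".join(rng.choice(list("ACGT"), 27))
                if seq not in table:
                    table[seq] = int(rng.integers(1, 400))
            assert collapse_errors(table, max_distance, ratio) == oracle_collapse(
                table, max_distance, ratio
            )

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_order_invariance(self, seed):
        """Result does not depend on input dict ordering."""
        rng = np.random.default_rng(seed)
        base = "".join(rng.choice(list("ACGT"), 27))
        items = {base: 500}
        for _ in range(int(rng.integers(1, 6))):
            pos = rng.choice(27, size=int(rng.integers(1, 3)), replace=False)
            items[mutate(base, pos, rng.choice(list("ACGT")))] = int(
                rng.integers(1, 600)
            )
        shuffled = dict(
            sorted(items.items(), key=lambda kv: rng.random())
        )
        assert collapse_errors(items, 2, 1 / 8) == collapse_errors(shuffled, 2, 1 / 8)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            collapse_errors({BC: 1}, max_distance=0)
        with pytest.raises(ValueError):
            collapse_errors({BC: 1}, ratio_threshold=1.0)
        with pytest.raises(ValueError):
            collapse_errors({BC: 0})


# ---------------------------------------------------------------------------
# build_count_table
# ---------------------------------------------------------------------------


class TestBuildCountTable:
    def test_zero_error_equals_expected_counts(self, tiny_experiment):
        table, prov = ct.build_count_table(
            tiny_experiment["manifest"], tiny_experiment["library"]
        )
        exp = (
            tiny_experiment["expected_counts"]
            .sort_values(["mouse", "lineage", "barcode"])
            .reset_index(drop=True)
        )
        got = (
            table[["mouse", "lineage", "barcode", "reads"]]
            .sort_values(["mouse", "lineage", "barcode"])
            .reset_index(drop=True)
        )
        pd.testing.assert_frame_equal(got, exp, check_dtype=False)
        # read conservation: kept + rejected = total per sample
        for s in prov["samples"]:
            assert (
                s["kept_reads"] + s[REASON_INCOMPLETE] + s[REASON_FLANK]
                + s["library_id_mismatch"] == s["total_reads"]
            )

    def test_empty_fastq_sample_recorded(self, small_library, tmp_path):
        path = tmp_path / "empty.fastq"
        path.write_text("")
        manifest = pd.DataFrame(
            [{"fastq": str(path), "mouse": "m1", "lineage": "B"}]
        )
        table, prov = ct.build_count_table(manifest, small_library)
        assert table.empty
        assert prov["samples"][0]["total_reads"] == 0

    def test_missing_fastq_raises(self, small_library, tmp_path):
        manifest = pd.DataFrame(
            [{"fastq": str(tmp_path / "nope.fastq"), "mouse": "m1", "lineage": "B"}]
        )
        with pytest.raises(FileNotFoundError):
            ct.build_count_table(manifest, small_library)

    def test_noisy_reads_mostly_reassigned_to_true_parents(self, tmp_path):
        """With 1% per-base errors and collapse on, >= 99% of counted reads
        sit on true library barcodes."""
        lib = ct.generate_barcode_library(80, 3, seed=41)
        cfg = ct.SimulationConfig(
            n_cells_transplanted=60, transduction_fraction=0.5, n_mice=1,
            clone_type_distribution=ct.YOUNG_CLONE_TYPE_DISTRIBUTION,
            read_depth=50_000, error_rate=0.01,
            gfp_fraction_per_lineage={lin: 0.5 for lin in ct.LINEAGES}, seed=42,
        )
        res = ct.simulate_experiment(cfg, library=lib, outdir=tmp_path)
        table, _ = ct.build_count_table(res["manifest"], lib)
        truth_bcs = set(res["truth"]["barcode"])
        on_true = table[table["barcode"].isin(truth_bcs)]["reads"].sum()
        assert on_true / table["reads"].sum() >= 0.99
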