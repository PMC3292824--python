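"""Site-pattern counting and distance models against independent oracles."""

import math
import random
import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcodegap.distances import (
    SiteCounts,
    complete_deletion_columns,
    count_site_patterns,
    inter_specific_matrix,
    intra_specific_summary,
    jc_distance,
    k2p_distance,
    p_distance,
    pairwise_distance_matrix,
)
from barcodegap.io import AlignedRecord, LocusAlignment

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
BASES = "ACGT"


def naive_site_counts(a: str, b: str) -> SiteCounts:
    """Per-site reference loop: the brute-force oracle for pairwise deletion."""
    n = ts = tv = 0
    for x, y in zip(a, b):
        if x not in BASES or y not in BASES:
            continue
        n += 1
        if x == y:
            continue
        same_class = (x in PURINES) == (y in PURINES)
        if same_class:
            ts += 1
        else:
            tv += 1
    return SiteCounts(n, ts, tv)


def closed_form_k2p(P: float, Q: float) -> float:
    w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        return math.nan
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


class TestSiteCounts:
    def test_identity(self):
        c = count_site_patterns("ACGT" * 25, "ACGT" * 25)
        assert (c.n_compared, c.n_transitions, c.n_transversions) == (100, 0, 0)

    def test_single_transition(self):
        c = count_site_patterns("AG", "GG")
        assert (c.n_compared, c.n_transitions, c.n_transversions) == (2, 1, 0)

    def test_transversion_and_skips(self):
        # A-C transversion; gap, N, ? and IUPAC R all skipped pairwise
        c = count_site_patterns("AC-NR?", "CCCCCC")
        assert (c.n_compared, c.n_transitions, c.n_transversions) == (2, 0, 1)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length mismatch"):
            count_site_patterns("ACGT", "ACG")

    def test_empty_overlap_flagged(self):
        c = count_site_patterns("NNNN", "ACGT")
        assert c.empty_overlap
        assert math.isnan(k2p_distance(c))
        assert math.isnan(p_distance(c))

    def test_matches_naive_oracle_on_random_pairs(self):
        rng = random.Random(42)
        alphabet = "ACGT" + "-N?RYSWK"
        for _ in range(200):
            L = rng.randrange(1, 80)
            a = "".join(rng.choice(alphabet) for _ in range(L))
            b = "".join(rng.choice(alphabet) for _ in range(L))
            assert count_site_patterns(a, b) == naive_site_counts(a, b)

    def test_complete_deletion_excludes_columns_dataset_wide(self):
        seqs = ["ACGT", "AC-T", "ACGT"]
        excluded = complete_deletion_columns(seqs)
        assert excluded.tolist() == [False, False, True, False]
        # pair (0, 2) has no gap itself, but column 2 is still excluded
        c = count_site_patterns(seqs[0], seqs[2], "complete", excluded)
        assert c.n_compared == 3


class TestDistanceModels:
    def test_k2p_zero(self):
        assert k2p_distance(SiteCounts(100, 0, 0)) == 0.0

    def test_k2p_worked_example(self):
        # P=0.1, Q=0.05: d = -1/2 ln(0.75) - 1/4 ln(0.90) = 0.1701811651...
        d = k2p_distance(SiteCounts(100, 10, 5))
        assert d == pytest.approx(0.1701811651, abs=1e-9)

    def test_k2p_equals_jc_when_Q_is_2P(self):
        # Q = 2P makes the K2P correction collapse to Jukes-Cantor
        d = k2p_distance(SiteCounts(100, 5, 10))
        jc = -0.75 * math.log(1 - 4 * 0.15 / 3)
        assert d == pytest.approx(jc, abs=1e-12)
        assert jc_distance(SiteCounts(100, 5, 10)) == pytest.approx(jc, abs=1e-12)

    def test_p_distance_arithmetic(self):
        assert p_distance(SiteCounts(100, 0, 0)) == 0.0
        assert p_distance(SiteCounts(100, 10, 5)) == pytest.approx(0.15)

    def test_saturation_is_nan_not_clamped(self):
        assert math.isnan(k2p_distance(SiteCounts(100, 48, 4)))  # 1-2P-Q = 0
        assert math.isnan(k2p_distance(SiteCounts(100, 0, 50)))  # 1-2Q = 0
        assert math.isnan(jc_distance(SiteCounts(100, 40, 35)))  # p = 3/4

    @given(
        n=st.integers(10, 2000),
        ts=st.integers(0, 2000),
        tv=st.integers(0, 2000),
    )
    def test_k2p_dominates_p_distance(self, n, ts, tv):
        if ts + tv > n:
            return
        c = SiteCounts(n, ts, tv)
        d = k2p_distance(c)
        if not math.isnan(d):
            assert d >= p_distance(c) - 1e-15
            if ts + tv == 0:
                assert d == 0.0
            else:
                assert d > 0.0

    def test_k2p_strictly_increasing_in_each_count(self):
        base = SiteCounts(1000, 50, 30)
        d0 = k2p_distance(base)
        assert k2p_distance(SiteCounts(1000, 51, 30)) > d0
        assert k2p_distance(SiteCounts(1000, 50, 31)) > d0


class TestDistanceMatrix:
    def test_identical_pair_zero_matrix(self):
        dm = pairwise_distance_matrix({"x": "ACGT" * 10, "y": "ACGT" * 10})
        assert dm.values.tolist() == [[0.0, 0.0], [0.0, 0.0]]
        assert not dm.undefined_mask.any()

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(5)
        seqs = {
            f"t{i}": "".join(rng.choice(list("ACGT-N"), size=60)) for i in range(6)
        }
        for model in ("p", "jc", "k2p"):
            dm = pairwise_distance_matrix(seqs, model=model)
            assert np.allclose(np.diag(dm.values), 0.0)
            assert np.array_equal(
                np.isnan(dm.values), np.isnan(dm.values.T)
            )
            m = np.where(np.isnan(dm.values), -1.0, dm.values)
            assert np.allclose(m, m.T)

    def test_matrix_equals_elementwise_recompute(self):
        rng = np.random.default_rng(11)
        labels = [f"t{i}" for i in range(8)]
        seqs = {
            lab: "".join(rng.choice(list("ACGTN-"), size=120)) for lab in labels
        }
        dm = pairwise_distance_matrix(seqs, model="k2p")
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i == j:
                    continue
                expect = k2p_distance(naive_site_counts(seqs[a], seqs[b]))
                got = dm.values[i, j]
                assert (math.isnan(expect) and math.isnan(got)) or got == pytest.approx(
                    expect, abs=1e-12
                )

    def test_too_few_taxa(self):
        with pytest.raises(ValueError, match="at least 2"):
            pairwise_distance_matrix({"only": "ACGT"})

    def test_tsv_writes_na_for_undefined(self, tmp_path):
        # saturated pair: all sites transversions
        dm = pairwise_distance_matrix({"a": "A" * 60, "b": "C" * 60})
        assert dm.undefined_mask.sum() == 2
        out = tmp_path / "m.tsv"
        dm.write_tsv(out)
        assert "NA" in out.read_text()

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_against_ape_k80(self, tmp_path):
        """Independent cross-check: ape's dist.dna(model='K80', pairwise.deletion)."""
        from barcodegap.simulate import evolve_sequence

        rng = np.random.default_rng(17)
        labels = [f"t{i}" for i in range(5)]
        ancestor = "".join(rng.choice(list("ACGT"), size=300))
        seqs = {
            lab: evolve_sequence(ancestor, 0.02 + 0.04 * i, 2.0, rng)
            for i, lab in enumerate(labels)
        }
        fasta = tmp_path / "aln.fasta"
        fasta.write_text("".join(f">{k}\n{v}\n" for k, v in seqs.items()))
        script = tmp_path / "k80.R"
        script.write_text(
            'suppressMessages(library(ape));'
            f'a <- read.dna("{fasta}", format="fasta");'
            'd <- dist.dna(a, model="K80", pairwise.deletion=TRUE);'
            'write.csv(as.matrix(d), stdout())'
        )
        res = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        lines = [l for l in res.stdout.strip().splitlines() if l]
        header = lines[0].split(",")[1:]
        ape_vals = {
            row.split(",")[0].strip('"'): [float(x) for x in row.split(",")[1:]]
            for row in lines[1:]
        }
        dm = pairwise_distance_matrix(seqs, model="k2p")
        for a, b, d in dm.pairs():
            j = header.index(f'"{b}"') if f'"{b}"' in header else header.index(b)
            assert d == pytest.approx(ape_vals[a][j], abs=1e-6)


class TestIntraInterSummaries:
    def test_identical_conspecifics_give_zero_max(self, toy_dataset):
        aln = toy_dataset.loci["locusB"]
        summ = intra_specific_summary(aln)
        assert summ.per_species == {"spA": (0.0,)}
        assert summ.intra_max == 0.0

    def test_singletons_excluded(self, toy_dataset):
        summ = intra_specific_summary(toy_dataset.loci["locusA"])
        assert set(summ.per_species) == {"spA", "spB"}  # spC singleton out
        assert summ.n_species == 2
        # spA: pairs (a1,a2)=0, (a1,a3), (a2,a3) one transition over 10 sites
        assert len(summ.per_species["spA"]) == 3
        assert summ.intra_max > 0

    def test_no_multiaccession_species_warns_zero(self):
        aln = LocusAlignment(
            "solo",
            (
                AlignedRecord("x1", "ACGT", species_label="spX"),
                AlignedRecord("y1", "AGGT", species_label="spY"),
            ),
        )
        summ = intra_specific_summary(aln)
        assert summ.intra_max == 0.0
        assert summ.warnings

    def test_inter_matrix_single_transition_closed_form(self):
        # one transition over 100 sites: P=0.01, Q=0 -> -1/2 ln(0.98)
        a = "ACGT" * 25
        b = "G" + a[1:]
        dm = inter_specific_matrix({"sp1": a, "sp2": b})
        expect = -0.5 * math.log(1 - 2 * 0.01)
        assert dm.get("sp1", "sp2") == pytest.approx(expect, abs=1e-12)

    def test_all_identical_representatives(self):
        dm = inter_specific_matrix({f"s{i}": "ACGT" * 10 for i in range(4)})
        mean, (lo, hi) = dm.mean_and_range()
        assert (mean, lo, hi) == (0.0, 0.0, 0.0)

    def test_inter_needs_two_species(self):
        with pytest.raises(ValueError, match="at least 2"):
            inter_specific_matrix({"only": "ACGT"})
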