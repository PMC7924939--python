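import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from carrierphylo.conservation import (A_SPECIFIC, B_SPECIFIC, LOW_COVERAGE,
                                       SHARED, VARIABLE, ConservationError,
                                       classify_positions, column_entropy,
                                       entropy_profile, extract_site_states,
                                       reference_column_map)
from carrierphylo.io_formats import Alignment, SeqRecord


def make_aln(rows):
    return Alignment([SeqRecord(k, v) for k, v in rows.items()])


class TestColumnEntropy:
    def test_uniform_column_zero(self):
        assert column_entropy("AAAA") == 0.0

    def test_even_binary_split_one_bit(self):
        assert column_entropy("AACC") == pytest.approx(1.0)

    def test_uniform_over_twenty(self):
        col = "ARNDCQEGHILKMFPSTVWY"
        assert column_entropy(col) == pytest.approx(math.log2(20))

    def test_gaps_excluded_by_default(self):
        assert column_entropy("AA--") == 0.0

    def test_gap_as_symbol_policy(self):
        assert column_entropy("AA--", gap_policy="symbol") == \
               pytest.approx(1.0)

    def test_all_removed_gives_sentinel(self):
        assert column_entropy("--XX") is None

    def test_base_configurable(self):
        assert column_entropy("AACC", base=math.e) == \
               pytest.approx(math.log(2))

    def test_matches_direct_formula_on_random_columns(self, rng):
        aa = list("ARNDCQEGHILKMFPSTVWY")
        for _ in range(1000):
            col = "".join(rng.choice(aa, size=int(rng.integers(1, 30))))
            h = column_entropy(col)
            counts = Counter(col)
            n = len(col)
            direct = -sum((c / n) * math.log2(c / n)
                          for c in counts.values())
            assert h == pytest.approx(direct, abs=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(st.text(alphabet="ARNDC", min_size=2, max_size=20),
           st.permutations(list("ARNDC")))
    def test_invariant_to_row_order_and_relabeling(self, col, perm):
        mapping = dict(zip("ARNDC", perm))
        relabeled = "".join(mapping[c] for c in col)
        shuffled = "".join(sorted(col))
        assert column_entropy(col) == pytest.approx(
            column_entropy(shuffled), abs=1e-12)
        assert column_entropy(col) == pytest.approx(
            column_entropy(relabeled), abs=1e-12)


class TestEntropyProfile:
    def test_reference_gap_mapping(self):
        aln = make_aln({"ref": "A-CD", "x": "AWCD"})
        cols = reference_column_map(aln, "ref")
        assert cols == [0, 2, 3]       # positions 1,2,3 -> columns 1,3,4

    def test_mapping_is_bijection(self, sim_truth):
        aln = sim_truth.alignment
        ref = aln.ids()[0]
        cols = reference_column_map(aln, ref)
        assert len(cols) == len(set(cols))
        assert len(cols) == len(aln.row(ref).ungapped())

    def test_clade_split_entropies(self):
        aln = make_aln({"a1": "AC", "a2": "AC", "ref": "AC",
                        "b1": "AA", "b2": "AR", "b3": "AN", "b4": "AD"})
        clades = {"a1": "A", "a2": "A", "ref": "A",
                  "b1": "B", "b2": "B", "b3": "B", "b4": "B"}
        tab = entropy_profile(aln, "ref", clades)
        assert tab.loc[1, "H_cladeA"] == 0.0
        assert tab.loc[1, "H_cladeB"] == pytest.approx(2.0)
        assert tab.loc[0, "H_all"] == 0.0

    def test_zero_entropy_means_single_residue(self, sim_truth):
        rows = [l for l, c in sim_truth.clade_of.items() if c == "A"]
        aln = sim_truth.alignment.subset(rows)
        ref = sorted(rows)[0]
        tab = entropy_profile(aln, ref, {r: "A" for r in rows})
        for _, row in tab.iterrows():
            if row["H_cladeA"] == 0.0:
                col = aln.column(int(row["column"]))
                assert len({c for c in col if c not in "-X"}) == 1

    def test_missing_reference_rejected(self):
        aln = make_aln({"x": "AC"})
        with pytest.raises(ConservationError):
            entropy_profile(aln, "nope", {"x": "A"})


class TestClassify:
    @staticmethod
    def table(ha, hb, ca="C", cb="C", cov=1.0):
        return pd.DataFrame([{
            "ref_pos": 1, "column": 0, "H_cladeA": ha, "H_cladeB": hb,
            "H_all": max(ha or 0, hb or 0), "consensus_A": ca,
            "consensus_freq_A": 1.0, "consensus_B": cb,
            "consensus_freq_B": 1.0, "coverage_A": cov, "coverage_B": cov,
        }])

    def test_conserved_same_consensus_is_shared(self):
        out = classify_positions(self.table(0.1, 0.2, "C", "C"))
        assert out.category[0] == SHARED

    def test_conserved_different_consensus_is_specific(self):
        # both clades fixed, different residue (the Cys-vs-Thr pattern):
        # conserved in A with a different B consensus counts as A-specific
        out = classify_positions(self.table(0.0, 0.0, "C", "T"))
        assert out.category[0] == A_SPECIFIC

    def test_conserved_only_in_b_is_b_specific(self):
        out = classify_positions(self.table(2.5, 0.1))
        assert out.category[0] == B_SPECIFIC

    def test_threshold_is_strict(self):
        out = classify_positions(self.table(0.5, 0.5), threshold=0.5)
        assert out.category[0] == VARIABLE

    def test_low_coverage_wins(self):
        out = classify_positions(self.table(0.0, 0.0, cov=0.2))
        assert out.category[0] == LOW_COVERAGE

    def test_planted_sites_recovered(self):
        """Mean A-specific precision/recall over replicates (single-seed
        values fluctuate with clade sizes; the mean is the contract)."""
        from carrierphylo.simulate import (SimConfig, sim_gene_family,
                                           sim_sequences)
        precs, recs = [], []
        for seed in range(60, 70):
            cfg = SimConfig(seed=seed)
            truth = sim_sequences(sim_gene_family(cfg), cfg)
            rows = [l for l, c in truth.clade_of.items() if c in ("A", "B")]
            aln = truth.alignment.subset(rows)
            ref = sorted(l for l, c in truth.clade_of.items()
                         if c == "A")[0]
            tab = classify_positions(entropy_profile(
                aln, ref, {l: truth.clade_of[l] for l in rows}))
            lab = np.array(truth.site_labels)
            called = set(tab.loc[tab.category == A_SPECIFIC, "column"])
            true = (set(np.flatnonzero(lab == "A_specific"))
                    & set(tab["column"]))
            tp = len(called & true)
            precs.append(tp / max(len(called), 1))
            recs.append(tp / len(true))
        assert np.mean(precs) >= 0.9
        assert np.mean(recs) >= 0.9

    def test_entropy_ordering_by_site_class(self, sim_truth):
        """Subfamily-wide entropy: invariant < clade-specific < neutral."""
        rows = [l for l, c in sim_truth.clade_of.items() if c in ("A", "B")]
        aln = sim_truth.alignment.subset(rows)
        ref = sorted(rows)[0]
        clades = {l: sim_truth.clade_of[l] for l in rows}
        tab = entropy_profile(aln, ref, clades)
        lab = np.array(sim_truth.site_labels)
        means = {}
        for cls in ("invariant", "A_specific", "neutral"):
            cols = set(np.flatnonzero(lab == cls)) & set(tab["column"])
            sel = tab[tab["column"].isin(cols)]
            means[cls] = sel["H_all"].mean()
        assert means["invariant"] < means["A_specific"] < means["neutral"]


class TestSiteStates:
    def test_reference_reports_its_own_residue(self):
        aln = make_aln({"ref": "A-CD", "x": "AWCD"})
        tab = extract_site_states(aln, "ref", [1, 2, 3])
        ref_row = tab[tab.leaf == "ref"].iloc[0]
        assert (ref_row["pos1"], ref_row["pos2"], ref_row["pos3"]) == \
               ("A", "C", "D")

    def test_deletion_reported_as_gap(self):
        aln = make_aln({"ref": "ACD", "x": "A-D"})
        tab = extract_site_states(aln, "ref", [2])
        assert tab[tab.leaf == "x"].iloc[0]["pos2"] == "-"

    def test_out_of_range_rejected(self):
        aln = make_aln({"ref": "ACD", "x": "ACD"})
        with pytest.raises(ConservationError):
            extract_site_states(aln, "ref", [4])

    def test_clade_specific_substitution_visible(self, sim_truth):
        lab = np.array(sim_truth.site_labels)
        rows = [l for l, c in sim_truth.clade_of.items() if c in ("A", "B")]
        aln = sim_truth.alignment.subset(rows)
        ref = sorted(l for l, c in sim_truth.clade_of.items()
                     if c == "A")[0]
        cols = reference_column_map(aln, ref)
        a_sites = [i + 1 for i, c in enumerate(cols)
                   if lab[c] == "A_specific"]
        tab = extract_site_states(aln, ref, a_sites[:3],
                                  {l: sim_truth.clade_of[l] for l in rows})
        for pos in a_sites[:3]:
            vals = tab.loc[tab.clade == "A", f"pos{pos}"]
            residues = {v for v in vals if v not in "-X"}
            assert len(residues) == 1     # frozen within clade A
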