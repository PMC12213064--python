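"""Ancestral-proteome reconstruction, retention and loss partition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tinygenome import ConfigurationError
from tinygenome.content import (
    LossLedger,
    OrthogroupMatrix,
    compute_retention,
    infer_ancestral_proteome,
    partition_losses,
    read_category_map,
    summarize_categories,
    truncate_pct,
)
from tinygenome.simulate import generate_orthogroup_matrix

ROLES8 = {"B1": "basal", "B2": "basal", "S1": "sister", "S2": "sister",
          "S3": "sister", "T1": "target", "T2": "target", "X1": "other"}


def matrix_of(df: pd.DataFrame, roles=None) -> OrthogroupMatrix:
    return OrthogroupMatrix(df, roles or {c: ROLES8[c] for c in df.columns})


def random_matrix(rng, n_og=60, taxa=tuple(ROLES8)) -> OrthogroupMatrix:
    df = pd.DataFrame(rng.integers(0, 2, size=(n_og, len(taxa))),
                      index=[f"OG{i}" for i in range(n_og)], columns=list(taxa))
    return matrix_of(df)


def brute_force_ancestral(m: OrthogroupMatrix) -> set[str]:
    basal = [t for t, r in m.roles.items() if r == "basal"]
    sister = [t for t, r in m.roles.items() if r == "sister"]
    return {
        og for og in m.presence.index
        if any(m.presence.loc[og, t] for t in basal)
        and any(m.presence.loc[og, t] for t in sister)
    }


class TestAncestralProteome:
    def test_basal_only_excluded(self):
        df = pd.DataFrame({"B1": [1], "B2": [0], "S1": [0], "S2": [0],
                           "S3": [0], "T1": [0], "T2": [0], "X1": [0]},
                          index=["og1"])
        assert infer_ancestral_proteome(matrix_of(df)) == set()

    def test_basal_and_sister_included_regardless_of_targets(self):
        df = pd.DataFrame({"B1": [1], "B2": [0], "S1": [1], "S2": [0],
                           "S3": [0], "T1": [0], "T2": [0], "X1": [0]},
                          index=["og1"])
        assert infer_ancestral_proteome(matrix_of(df)) == {"og1"}

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(55)
        for _ in range(30):
            m = random_matrix(rng)
            assert infer_ancestral_proteome(m) == brute_force_ancestral(m)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(56)
        m = random_matrix(rng)
        df = m.presence.astype(int)
        shuffled = df.sample(frac=1, random_state=1)[list(rng.permutation(df.columns))]
        assert infer_ancestral_proteome(matrix_of(shuffled)) == \
            infer_ancestral_proteome(m)

    def test_missing_role_rejected(self):
        df = pd.DataFrame({"B1": [1], "T1": [1]}, index=["og1"])
        with pytest.raises(ConfigurationError):
            OrthogroupMatrix(df, {"B1": "basal", "T1": "target"})


class TestRetention:
    def test_paper_arithmetic_truncates(self):
        assert truncate_pct(477, 2151) == 22.1
        assert truncate_pct(402, 2151) == 18.6

    def test_retention_counts_and_percentage(self):
        n = 20
        ogs = [f"og{i}" for i in range(n)]
        df = pd.DataFrame(1, index=ogs, columns=list(ROLES8))
        df.loc[ogs[7:], "T1"] = 0  # T1 keeps 7 of 20
        m = matrix_of(df)
        ancestral = infer_ancestral_proteome(m)
        assert len(ancestral) == n
        count, pct = compute_retention(ancestral, m, "T1")
        assert (count, pct) == (7, 35.0)

    def test_zero_retention(self):
        df = pd.DataFrame(1, index=["og1"], columns=list(ROLES8))
        df["T1"] = 0
        m = matrix_of(df)
        assert compute_retention({"og1"}, m, "T1") == (0, 0.0)

    def test_empty_ancestral_percentage_undefined(self):
        df = pd.DataFrame(1, index=["og1"], columns=list(ROLES8))
        m = matrix_of(df)
        assert compute_retention(set(), m, "T1") == (0, None)

    def test_non_target_taxon_rejected(self):
        df = pd.DataFrame(1, index=["og1"], columns=list(ROLES8))
        with pytest.raises(ConfigurationError):
            compute_retention({"og1"}, matrix_of(df), "B1")

    @given(st.integers(0, 2**31 - 1))
    def test_adding_a_loss_never_raises_retention(self, seed):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng, n_og=30)
        ancestral = infer_ancestral_proteome(m)
        if not ancestral:
            return
        _, pct = compute_retention(ancestral, m, "T1")
        present = [og for og in ancestral if m.presence.loc[og, "T1"]]
        if not present:
            return
        df = m.presence.astype(int).copy()
        df.loc[str(rng.choice(present)), "T1"] = 0
        _, pct2 = compute_retention(ancestral, matrix_of(df), "T1")
        assert pct2 <= pct


class TestPartitionLosses:
    def test_enumerable_example(self):
        df = pd.DataFrame(0, index=["a", "b", "c"], columns=list(ROLES8))
        df.loc[:, ["B1", "S1"]] = 1          # all three ancestral
        df.loc["a", "T1"] = 1                # T1 has {a}
        df.loc[["a", "b"], "T2"] = 1         # T2 has {a, b}
        m = matrix_of(df)
        ledger = partition_losses({"a", "b", "c"}, m, ["T1", "T2"])
        assert ledger.shared_loss == {"c"}
        assert ledger.specific_loss["T1"] == {"b"}
        assert ledger.specific_loss["T2"] == set()
        assert ledger.retained["T1"] == {"a"}

    def test_identical_target_columns_have_no_specific_losses(self):
        rng = np.random.default_rng(9)
        m = random_matrix(rng, n_og=40)
        df = m.presence.astype(int).copy()
        df["T2"] = df["T1"]
        m2 = matrix_of(df)
        ancestral = infer_ancestral_proteome(m2)
        ledger = partition_losses(ancestral, m2)
        assert all(not s for s in ledger.specific_loss.values())

    @given(st.integers(0, 2**31 - 1))
    def test_classes_partition_ancestral_exactly(self, seed):
        m = random_matrix(np.random.default_rng(seed), n_og=40)
        ancestral = infer_ancestral_proteome(m)
        ledger = partition_losses(ancestral, m)
        for t in ledger.targets:
            union = ledger.retained[t] | ledger.shared_loss | ledger.specific_loss[t]
            assert union == ancestral
            assert len(ledger.retained[t]) + len(ledger.shared_loss) \
                + len(ledger.specific_loss[t]) == len(ancestral)

    def test_simulated_losses_match_generator_truth(self):
        df, roles, truth = generate_orthogroup_matrix(n_orthogroups=800, seed=17)
        m = OrthogroupMatrix(df, roles)
        ancestral = infer_ancestral_proteome(m)
        ledger = partition_losses(ancestral, m, ["T1", "T2"])
        losses = {b: set(v) for b, v in truth["losses"].items()}
        lost = {t: losses["inner"] | losses["target_mrca"] | losses[f"tip:{t}"]
                for t in ("T1", "T2")}
        # independent route: reconstruct the ledger from the recorded events
        assert ledger.shared_loss == ancestral & lost["T1"] & lost["T2"]
        assert ledger.specific_loss["T1"] == ancestral & (lost["T1"] - lost["T2"])
        assert ledger.retained["T1"] == ancestral - lost["T1"]


class TestCategories:
    def make_ledger(self):
        df = pd.DataFrame(0, index=list("abcdef"), columns=list(ROLES8))
        df.loc[:, ["B1", "S2"]] = 1
        df.loc[["a", "b"], ["T1", "T2"]] = 1
        df.loc["c", "T1"] = 1
        m = matrix_of(df)
        return partition_losses(infer_ancestral_proteome(m), m)

    def test_single_category_equals_ledger_counts(self):
        ledger = self.make_ledger()
        table = summarize_categories(ledger, {og: "cat" for og in "abcdef"})
        row = table.loc["cat"]
        assert row["shared_loss"] == len(ledger.shared_loss)
        assert row["retained_all"] == 2
        assert row["ancestral_total"] == 6

    def test_empty_map_everything_uncategorized(self):
        table = summarize_categories(self.make_ledger(), {})
        assert table.loc["uncategorized", "ancestral_total"] == 6

    def test_random_map_conserves_per_category_totals(self):
        rng = np.random.default_rng(12)
        ledger = self.make_ledger()
        cmap = {og: f"c{rng.integers(3)}" for og in "abcde"}  # 'f' unmapped
        table = summarize_categories(ledger, cmap)
        class_cols = [c for c in table.columns if c != "ancestral_total"]
        assert (table[class_cols].sum(axis=1) == table["ancestral_total"]).all()
        assert table["ancestral_total"].sum() == len(ledger.ancestral)

    def test_malformed_map_rows_skipped(self, tmp_path):
        p = tmp_path / "cats.tsv"
        p.write_text("og1\ttransport\nbadline\nog2\tregulation\n\t\n")
        assert read_category_map(p) == {"og1": "transport", "og2": "regulation"}
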