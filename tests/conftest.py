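import numpy as np
import pytest
from hypothesis import settings

from tinygenome.hcaa import MarkerAlignment
from tinygenome.simulate import SimConfig, generate_marker_families, generate_target_genome

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

AA = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_hcaa(alignment: MarkerAlignment, threshold: float = 0.90):
    """Independent column-scan oracle: (column, consensus, fraction) tuples."""
    out = []
    n = alignment.n_sequences
    for col in range(alignment.n_columns):
        column = [seq[col] for seq in alignment.sequences]
        best_aa, best = None, 0
        tie = False
        for aa in AA:
            c = column.count(aa)
            if c > best:
                best_aa, best, tie = aa, c, False
            elif c == best and c > 0:
                tie = True
        if best_aa is not None and not tie and best / n >= threshold:
            out.append((col, best_aa, best / n))
    return out


def random_alignment(rng: np.random.Generator, n_seqs=12, n_cols=40,
                     family_id="rand", gap_prob=0.05) -> MarkerAlignment:
    """Alignment with heavy column-wise skew so some columns pass 90%."""
    seqs = []
    anchor = rng.choice(list(AA), size=n_cols)
    stickiness = rng.uniform(0.3, 1.0, size=n_cols)
    for _ in range(n_seqs):
        row = []
        for c in range(n_cols):
            if rng.random() < gap_prob:
                row.append("-")
            elif rng.random() < stickiness[c]:
                row.append(anchor[c])
            else:
                row.append(str(rng.choice(list(AA))))
        seqs.append("".join(row))
    return MarkerAlignment(family_id, tuple(f"t{i}" for i in range(n_seqs)),
                           tuple(seqs))


@pytest.fixture(scope="session")
def small_standard_sim():
    """A compact standard-code simulation shared across tests."""
    cfg = SimConfig(seed=11, n_families=5, n_ref_taxa=30, family_length=120,
                    genetic_code="standard")
    families, truth_cols = generate_marker_families(cfg)
    genome, truth = generate_target_genome(families, cfg, truth_cols)
    return cfg, families, truth_cols, genome, truth


@pytest.fixture(scope="session")
def small_uga_sim():
    """A compact UGA=Trp simulation shared across tests."""
    cfg = SimConfig(seed=13, n_families=6, n_ref_taxa=30, family_length=150,
                    genetic_code="uga_trp", gc_target=0.32)
    families, truth_cols = generate_marker_families(cfg)
    genome, truth = generate_target_genome(families, cfg, truth_cols)
    return cfg, families, truth_cols, genome, truth
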