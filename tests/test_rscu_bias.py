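import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocub import (
    CodonCounts,
    SynthSpec,
    amino_acid_frequencies,
    compute_rscu,
    count_codons,
    generate_cds_set,
    get_genetic_code,
    hierarchical_cluster_order,
    preferred_codon_summary,
    rscu_matrix,
)

from conftest import random_counts


def _by_codon(entries):
    return {e.codon: e for e in entries}


def test_twofold_family_example(code5):
    """Lys {AAA:3, AAG:1} -> RSCU 1.5 / 0.5."""
    entries = _by_codon(compute_rscu(CodonCounts({"AAA": 3, "AAG": 1}), code5))
    assert entries["AAA"].rscu == pytest.approx(1.5)
    assert entries["AAG"].rscu == pytest.approx(0.5)
    assert entries["AAA"].category == "high"
    assert entries["AAG"].category == "under"


def test_uniform_counts_all_unbiased(code5):
    counts = CodonCounts({c: 7 for c in code5.sense_codons})
    entries = compute_rscu(counts, code5)
    assert all(e.rscu == pytest.approx(1.0) and e.category == "unbiased"
               for e in entries)
    assert preferred_codon_summary(entries) == {
        "n_over": 0, "n_high": 0, "n_preferred": 0}


def test_fourfold_family_single_codon(code5):
    fam = code5.family_of("V")  # GTN
    entries = _by_codon(compute_rscu(CodonCounts({"GTA": 9}), code5))
    assert entries["GTA"].rscu == pytest.approx(4.0)
    assert entries["GTA"].category == "over"
    for codon in fam.codons:
        if codon != "GTA":
            assert entries[codon].rscu == 0.0 and entries[codon].category == "under"


def test_absent_family_is_undefined(code5):
    entries = _by_codon(compute_rscu(CodonCounts({"AAA": 5}), code5))
    assert not entries["TGT"].defined  # no Cys observed
    assert entries["TGT"].rscu == 0.0
    # AAA monopolizes Lys (RSCU 2.0, over); undefined codons add nothing
    assert preferred_codon_summary(entries.values()) == {
        "n_over": 1, "n_high": 0, "n_preferred": 1}


@pytest.mark.parametrize("table_id", [1, 5])
def test_family_sums_equal_degeneracy(table_id, code5, code1):
    """Within every expressed family, RSCU values sum to the degeneracy."""
    code = code5 if table_id == 5 else code1
    rng = np.random.default_rng(42)
    for _ in range(50):
        entries = compute_rscu(random_counts(rng, code), code)
        sums: dict[str, float] = {}
        for e in entries:
            if e.defined:
                sums[e.amino_acid] = sums.get(e.amino_acid, 0.0) + e.rscu
        for aa, total in sums.items():
            assert total == pytest.approx(code.family_of(aa).degeneracy, abs=1e-9)


_SENSE5 = get_genetic_code(5).sense_codons


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.dictionaries(st.sampled_from(_SENSE5), st.integers(0, 500),
                       min_size=1))
def test_family_sum_property_arbitrary_counts(code5, raw_counts):
    """For arbitrary count vectors every expressed family's RSCU values sum
    to the degeneracy and undefined entries carry RSCU 0."""
    entries = compute_rscu(CodonCounts(raw_counts), code5)
    sums: dict[str, float] = {}
    for e in entries:
        if e.defined:
            sums[e.amino_acid] = sums.get(e.amino_acid, 0.0) + e.rscu
        else:
            assert e.rscu == 0.0
    for aa, total in sums.items():
        assert total == pytest.approx(code5.family_of(aa).degeneracy, abs=1e-9)


def test_rscu_invariant_under_count_scaling(code5):
    rng = np.random.default_rng(8)
    counts = random_counts(rng, code5)
    base = {e.codon: e.rscu for e in compute_rscu(counts, code5)}
    scaled = {e.codon: e.rscu for e in compute_rscu(counts.scale(13), code5)}
    assert base == pytest.approx(scaled)


def test_amino_acid_frequencies(code5):
    freqs = amino_acid_frequencies(CodonCounts({"ATG": 2, "AAA": 2}), code5)
    assert freqs["M"] == pytest.approx(0.5)
    assert freqs["K"] == pytest.approx(0.5)
    rng = np.random.default_rng(2)
    freqs = amino_acid_frequencies(random_counts(rng, code5), code5)
    assert freqs.sum() == pytest.approx(1.0)
    with pytest.raises(ValueError):
        amino_acid_frequencies(CodonCounts({}), code5)


def test_at_ending_selection_raises_at_rscu(code5, fixture_records):
    """With AT-ending preference the mean RSCU of A/T-ending codons exceeds
    that of G/C-ending codons."""
    counts = count_codons(fixture_records[0], code5)
    for rec in fixture_records[1:]:
        counts = counts + count_codons(rec, code5)
    rscu = {e.codon: e.rscu for e in compute_rscu(counts, code5) if e.defined}
    at = np.mean([v for c, v in rscu.items() if c[2] in "AT"])
    gc = np.mean([v for c, v in rscu.items() if c[2] in "GC"])
    assert at > gc


# ---------------------------------------------------------------------------
# heatmap clustering
# ---------------------------------------------------------------------------

def test_identical_rows_cluster_adjacent(code5):
    rng = np.random.default_rng(4)
    counts = random_counts(rng, code5)
    units = {"a": counts, "b": random_counts(rng, code5), "a2": counts}
    matrix = rscu_matrix(units, code5)
    row_order, _ = hierarchical_cluster_order(matrix)
    labels = [matrix.row_labels[i] for i in row_order]
    assert abs(labels.index("a") - labels.index("a2")) == 1


def test_two_bias_regimes_bipartition(code5):
    """Rows from neutral (s=0) vs strong AT-selection (s=3) regimes separate:
    every within-regime distance is smaller than every between-regime one."""
    lengths = {"G1": 400}
    rows = {}
    for s, tag in ((0.0, "neutral"), (3.0, "selected")):
        spec = SynthSpec(n_species=3, gene_lengths=lengths, theta_gc3=0.5,
                         selection_s=s, seed=77)
        for rec in generate_cds_set(spec):
            rows[f"{tag}-{rec.species}"] = count_codons(rec, code5)
    matrix = rscu_matrix(rows, code5)
    values = matrix.values
    labels = list(values.index)
    # exhaustive pairwise distances: regimes must be separable
    within, between = [], []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            d = float(np.linalg.norm(values.loc[a] - values.loc[b]))
            (within if a.split("-")[0] == b.split("-")[0] else between).append(d)
    assert max(within) < min(between)
    row_order, _ = hierarchical_cluster_order(matrix)
    ordered = [labels[i].split("-")[0] for i in row_order]
    assert ordered[:3] == ["neutral"] * 3 or ordered[:3] == ["selected"] * 3


def test_cluster_order_deterministic_and_permutation_stable(code5):
    """Repeat calls give identical orderings, and permuting the input rows of
    a two-regime matrix leaves the top-level bipartition intact."""
    lengths = {"G1": 400}
    rows = {}
    for s, tag in ((0.0, "neutral"), (3.0, "selected")):
        spec = SynthSpec(n_species=3, gene_lengths=lengths, theta_gc3=0.5,
                         selection_s=s, seed=78)
        for rec in generate_cds_set(spec):
            rows[f"{tag}-{rec.species}"] = count_codons(rec, code5)
    matrix = rscu_matrix(rows, code5)
    assert hierarchical_cluster_order(matrix) == hierarchical_cluster_order(matrix)
    rng = np.random.default_rng(12)
    keys = list(rows)
    rng.shuffle(keys)
    matrix2 = rscu_matrix({k: rows[k] for k in keys}, code5)
    for m in (matrix, matrix2):
        order, _ = hierarchical_cluster_order(m)
        regimes = [m.row_labels[i].split("-")[0] for i in order]
        assert regimes[:3] == [regimes[0]] * 3 and regimes[3:] == [regimes[3]] * 3


def test_unsupported_metric_rejected(code5):
    rng = np.random.default_rng(1)
    matrix = rscu_matrix({"a": random_counts(rng, code5),
                          "b": random_counts(rng, code5)}, code5)
    with pytest.raises(ValueError):
        hierarchical_cluster_order(matrix, metric="no-such-metric")
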