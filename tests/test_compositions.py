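"""Venom/diet containers, cleaning rules and the two diversity indices."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from venomdiet import compositions as comp
from venomdiet.errors import DataFormatError, ValidationError

positive_vectors = st.lists(
    st.floats(min_value=1e-6, max_value=1e3, allow_nan=False), min_size=1, max_size=12
)


# ---------------------------------------------------------------------------
# indices
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "p, shannon, simpson",
    [
        ([0.25, 0.25, 0.25, 0.25], math.log(4), 0.75),
        ([1.0], 0.0, 0.0),
        ([0.5, 0.25, 0.25], 1.039721, 0.625),
    ],
)
def test_index_values(p, shannon, simpson):
    assert comp.shannon_index(p) == pytest.approx(shannon, abs=1e-6)
    assert comp.simpson_index(p) == pytest.approx(simpson, abs=1e-6)


def test_indices_reject_degenerate_vectors():
    for bad in ([0.0, 0.0], [-0.1, 1.1]):
        with pytest.raises(ValidationError):
            comp.shannon_index(bad)
        with pytest.raises(ValidationError):
            comp.simpson_index(bad)


def test_indices_match_scikit_bio():
    """Cross-check against an independent implementation on random vectors."""
    from skbio.diversity.alpha import shannon, simpson

    rng = np.random.default_rng(7)
    for _ in range(25):
        counts = rng.integers(1, 200, size=rng.integers(2, 10))
        assert comp.shannon_index(counts) == pytest.approx(
            float(shannon(counts, base=math.e)), abs=1e-12
        )
        assert comp.simpson_index(counts) == pytest.approx(
            float(simpson(counts)), abs=1e-12
        )


@settings(derandomize=True, max_examples=100, deadline=None)
@given(positive_vectors, st.randoms(use_true_random=False))
def test_permutation_and_zero_padding_invariance(p, rnd):
    shuffled = list(p)
    rnd.shuffle(shuffled)
    padded = shuffled + [0.0, 0.0]
    for fn in (comp.shannon_index, comp.simpson_index):
        ref = fn(p)
        assert fn(shuffled) == pytest.approx(ref, abs=1e-9)
        assert fn(padded) == pytest.approx(ref, abs=1e-9)


@pytest.mark.parametrize("r", range(1, 11))
def test_uniform_vector_maximizes_both_indices(r):
    uniform = [1.0 / r] * r
    assert comp.shannon_index(uniform) == pytest.approx(math.log(r), abs=1e-12)
    assert comp.simpson_index(uniform) == pytest.approx(1 - 1 / r, abs=1e-12)
    rng = np.random.default_rng(r)
    for _ in range(20):
        p = rng.dirichlet(np.full(r, 0.5))
        assert comp.shannon_index(p) <= math.log(r) + 1e-12
        assert comp.simpson_index(p) <= 1 - 1 / r + 1e-12


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.lists(st.floats(min_value=1e-6, max_value=1e3), min_size=2, max_size=12))
def test_merging_categories_never_increases_diversity(p):
    merged = [p[0] + p[1]] + list(p[2:])
    assert comp.shannon_index(merged) <= comp.shannon_index(p) + 1e-9
    assert comp.simpson_index(merged) <= comp.simpson_index(p) + 1e-9


def test_index_sampling_variance_matches_monte_carlo():
    """Delta-method variance of the plug-in index vs direct resampling."""
    rng = np.random.default_rng(3)
    p = np.array([0.5, 0.3, 0.15, 0.05])
    n = 200
    for index in ("shannon", "simpson"):
        stats = [
            comp.diversity(rng.multinomial(n, p), index) for _ in range(4000)
        ]
        predicted = comp.index_sampling_variance(n * p, index)
        assert np.var(stats) == pytest.approx(predicted, rel=0.15)


# ---------------------------------------------------------------------------
# venom I/O and cleaning
# ---------------------------------------------------------------------------

def test_read_venom_profiles(venom_csv):
    profiles = comp.read_venom_profiles(venom_csv)
    assert [p.record_id for p in profiles] == ["r1", "r2", "r3"]
    r1 = profiles[0]
    assert r1.raw_total_percent == pytest.approx(100.0)
    assert r1.species_id == "Naja naja"
    assert r1.method == "proteome"
    assert set(r1.components) == {"3FTx", "PLA2", "SVMP"}


def test_read_venom_rejects_negative_and_duplicates(tmp_path):
    header = "species,record_id,source,method,toxin_family,percent_abundance\n"
    bad_sign = tmp_path / "neg.csv"
    bad_sign.write_text(header + "A,r1,s,proteome,3FTx,-5\n")
    with pytest.raises(ValidationError, match="negative"):
        comp.read_venom_profiles(bad_sign)
    dup = tmp_path / "dup.csv"
    dup.write_text(header + "A,r1,s,proteome,3FTx,10\nA,r1,s,proteome,3FTx,20\n")
    with pytest.raises(ValidationError, match="duplicate"):
        comp.read_venom_profiles(dup)
    empty = tmp_path / "empty.csv"
    empty.write_text(header)
    assert comp.read_venom_profiles(empty) == []
    missing = tmp_path / "missing.csv"
    missing.write_text("species,record_id\nA,r1\n")
    with pytest.raises(DataFormatError, match="missing required column"):
        comp.read_venom_profiles(missing)


def test_clean_venom_profiles(venom_csv):
    profiles = comp.read_venom_profiles(venom_csv)
    retained, report = comp.clean_venom_profiles(profiles)
    assert report.n_input == 3
    assert report.removed_ids == [("r3", "total_above_cap")]
    assert [p.record_id for p in retained] == ["r1", "r2"]
    for p in retained:
        assert p.abundances.sum() == pytest.approx(1.0, abs=1e-9)
    # 52.1/52.1 out of 104.2 total renormalizes to an even split
    assert retained[1].components == pytest.approx({"3FTx": 0.5, "PLA2": 0.5})
    # ratios preserved exactly by renormalization
    r1 = retained[0].components
    assert r1["3FTx"] / r1["PLA2"] == pytest.approx(2.0, abs=1e-12)


def test_clean_is_idempotent(venom_csv):
    profiles = comp.read_venom_profiles(venom_csv)
    once, _ = comp.clean_venom_profiles(profiles)
    twice, report = comp.clean_venom_profiles(once)
    assert report.n_removed == 0
    for a, b in zip(once, twice):
        assert a.components == pytest.approx(b.components, abs=1e-15)


# ---------------------------------------------------------------------------
# diet
# ---------------------------------------------------------------------------

def _diet_frame(rows):
    return pd.DataFrame(rows, columns=["species", "prey_family", "prey_order", "n_records"])


def test_aggregate_diet_sums_duplicate_labels():
    records = _diet_frame(
        [("sp1", "Muridae", "Rodentia", 3), ("sp1", "Muridae", "Rodentia", 2)]
    )
    (fam,) = comp.aggregate_diet(records, "family")
    assert fam.counts == {"Muridae": 5}
    (order,) = comp.aggregate_diet(records, "order")
    assert order.counts == {"Rodentia": 5}
    two = comp.aggregate_diet(
        _diet_frame([("sp1", "Muridae", "Rodentia", 3), ("sp2", "Bufonidae", "Anura", 1)]),
        "family",
    )
    assert [t.species_id for t in two] == ["sp1", "sp2"]


def test_aggregate_diet_rejects_bad_counts():
    with pytest.raises(ValidationError):
        comp.aggregate_diet(_diet_frame([("sp1", "Muridae", "Rodentia", 0)]), "family")


def test_filter_diet_boundary():
    tables = [
        comp.DietCountTable("few", "family", {"Muridae": 4}),
        comp.DietCountTable("enough", "family", {"Muridae": 5}),
    ]
    kept, report = comp.filter_diet(tables)
    assert [t.species_id for t in kept] == ["enough"]
    assert report.removed_ids == [("few", "too_few_prey_items")]
    kept2, report2 = comp.filter_diet(kept)
    assert len(kept2) == 1 and report2.n_removed == 0  # idempotent
    empty_kept, empty_report = comp.filter_diet([])
    assert empty_kept == [] and empty_report.n_input == 0


def test_count_prey_taxa():
    rows = _diet_frame(
        [("sp", "A", "X", 1), ("sp", "B", "X", 1), ("sp", "C", "Y", 1)]
    )
    assert comp.count_prey_taxa(rows) == (3, 2)
    assert comp.count_prey_taxa(rows.iloc[0:0]) == (0, 0)
    # eleven families spread over nine orders (a black-mamba-like tally)
    fams = [f"F{i}" for i in range(11)]
    orders = [f"O{min(i, 8)}" for i in range(11)]
    big = _diet_frame([("sp", f, o, 1) for f, o in zip(fams, orders)])
    assert comp.count_prey_taxa(big) == (11, 9)


# ---------------------------------------------------------------------------
# joined table
# ---------------------------------------------------------------------------

def test_diversity_table_replicates_species_diet(venom_csv, diet_csv):
    # skip abundance cleaning here so Bitis arietans (4 diet records, filtered
    # out at both levels) is still present on the venom side of the join
    profiles = comp.read_venom_profiles(venom_csv)
    records = comp.read_diet_records(diet_csv)
    fam, _ = comp.filter_diet(comp.aggregate_diet(records, "family"), min_items=5)
    order, _ = comp.filter_diet(comp.aggregate_diet(records, "order"), min_items=5)
    table, dropped = comp.diversity_table(profiles, fam, order)
    assert dropped == ["Bitis arietans"]
    assert list(table["record_id"]) == ["r1", "r2"]
    # both venomic records of Naja naja carry the same species-level diet values
    assert table["diet_shannon_family"].nunique() == 1
    expected = comp.shannon_index([5, 4])
    assert table["diet_shannon_family"].iloc[0] == pytest.approx(expected)


def test_diversity_table_level_gaps(venom_csv, diet_csv):
    profiles, _ = comp.clean_venom_profiles(comp.read_venom_profiles(venom_csv))
    records = comp.read_diet_records(diet_csv)
    fam, _ = comp.filter_diet(comp.aggregate_diet(records, "family"), min_items=5)
    table, _ = comp.diversity_table(profiles, fam, [])  # family level only
    assert table["diet_simpson_family"].notna().all()
    assert table["diet_simpson_order"].isna().all()
    fam_ds = comp.analysis_dataset(table, "simpson", "family")
    assert len(fam_ds) == 2
    order_ds = comp.analysis_dataset(table, "simpson", "order")
    assert order_ds.empty
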