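"""Site diversity, consensus/degeneracy classification, and filtering rules."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from divlen import diversity
from divlen.diversity import (
    CodonAlignment,
    OrthologTable,
    classify_sites,
    filter_orthologs,
    gene_diversity_vs_length,
    gene_silent_profile,
    jaccard_dereplicate,
    site_diversity,
    species_mean_profile,
)

BASES = "ACGT"


def brute_force_pi(column: str) -> float:
    """Oracle: mean of the 'bases differ' indicator over all sequence pairs."""
    pairs = list(itertools.combinations(column, 2))
    return sum(a != b for a, b in pairs) / len(pairs)


# ---------------------------------------------------------------------------
# site_diversity
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "counts,expected",
    [
        ({"A": 1, "C": 1}, 1.0),  # the single pair differs
        ({"A": 4}, 0.0),  # monomorphic
        ({"A": 2, "G": 2}, 4 / 6),  # 4 of 6 pairs differ
    ],
)
def test_site_diversity_examples(counts, expected):
    assert site_diversity(counts) == pytest.approx(expected, abs=1e-12)


def test_site_diversity_matches_pairwise_oracle(rng):
    """Formula equals brute-force pairwise comparison for random columns."""
    for _ in range(300):
        n = rng.integers(2, 21)
        column = "".join(rng.choice(list(BASES), size=n))
        counts = {b: column.count(b) for b in BASES}
        assert site_diversity(counts) == pytest.approx(
            brute_force_pi(column), abs=1e-12
        )


@given(
    st.lists(st.integers(min_value=0, max_value=30), min_size=4, max_size=4).filter(
        lambda f: sum(f) >= 2
    )
)
def test_site_diversity_relabeling_invariance(f):
    """pi depends only on the multiset of counts, not base identity."""
    base = site_diversity(f)
    assert 0.0 <= base <= 1.0
    for perm in itertools.permutations(f):
        assert site_diversity(list(perm)) == pytest.approx(base, abs=1e-12)


def test_site_diversity_undefined_below_two():
    with pytest.raises(ValueError):
        site_diversity({"A": 1})


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def _aln(rows, gene_id="g"):
    return CodonAlignment(gene_id, tuple(f"s{i}" for i in range(len(rows))), tuple(rows))


def test_consensus_threshold_boundary():
    # column 0: 3 A of 5 rows = 0.6 meets the 60% threshold exactly
    aln = _aln(["AGG", "AGG", "AGG", "CGG", "CGG"])
    cls = classify_sites(aln, consensus_threshold=0.6)
    assert cls.consensus[0] == "A"


def test_no_consensus_is_ambiguous():
    # 2 A, 2 C, 1 G: modal fraction 0.4 < 0.6
    aln = _aln(["AGG", "AGG", "CGG", "CGG", "GGG"])
    cls = classify_sites(aln)
    assert cls.consensus[0] is None
    assert cls.degeneracy[0] == diversity.AMBIGUOUS


def test_fourfold_degeneracy_from_consensus_codon():
    # GGA -> glycine, third position 4-fold under the standard code
    aln = _aln(["GGA", "GGA", "GGC"])
    cls = classify_sites(aln)
    assert cls.degeneracy[2] == 4
    assert cls.degeneracy[0] == 1  # first position of GGN is 1-fold


def test_gap_exclusion_rule():
    rows = ["GG-", "GG-", "GG-", "GGA"]  # 75% gaps in column 2
    cls = classify_sites(_aln(rows), max_gap_frac=0.7)
    assert cls.degeneracy[2] == diversity.EXCLUDED
    assert cls.gap_fraction[2] == pytest.approx(0.75)


def test_n_characters_count_as_gaps():
    rows = ["GGN", "GGN", "GGN", "GGA"]
    cls = classify_sites(_aln(rows), max_gap_frac=0.7)
    assert cls.degeneracy[2] == diversity.EXCLUDED


# ---------------------------------------------------------------------------
# gene profiles
# ---------------------------------------------------------------------------


def test_silent_rank_assignment_skips_non_fourfold():
    # gene: ATG (not 4-fold), GGA (4-fold), AAA (lysine: 2-fold), CCT (4-fold)
    rows = ["ATGGGAAAACCT"] * 3
    prof = gene_silent_profile(_aln(rows))
    positions = [p for p, _ in prof]
    assert positions == [0, 1]  # ranks over the two 4-fold sites only
    assert all(pi == 0.0 for _, pi in prof)  # identical rows


def test_excluded_column_shifts_ranks():
    clean = ["ATG" + "GGA" + "CCT"] * 4
    prof_clean = gene_silent_profile(_aln(clean))
    # make the first 4-fold column gappy: it must vanish and CCT becomes rank 0
    gappy = ["ATG" + "GG-" + "CCT"] * 3 + ["ATG" + "GGA" + "CCT"]
    prof_gappy = gene_silent_profile(_aln(gappy))
    assert [p for p, _ in prof_clean] == [0, 1]
    assert [p for p, _ in prof_gappy] == [0]


def test_bp_position_mode_reports_column_offsets():
    rows = ["ATGGGACCT"] * 3
    prof = gene_silent_profile(_aln(rows), position_mode="bp")
    assert [p for p, _ in prof] == [5, 8]


def test_row_order_invariance_of_profile(rng):
    rows = ["ATGGGAGGC", "ATGGGCGGC", "ATGGGAGGT", "ATGGGAGGC"]
    base = gene_silent_profile(_aln(rows))
    for _ in range(5):
        perm = list(rng.permutation(len(rows)))
        shuffled = gene_silent_profile(_aln([rows[i] for i in perm]))
        assert shuffled == base


# ---------------------------------------------------------------------------
# species profile
# ---------------------------------------------------------------------------


def test_species_mean_profile_weights_and_means():
    g1 = [(0, 0.2), (1, 0.1)]
    g2 = [(0, 0.4)]
    prof = species_mean_profile([g1, g2], max_sites=500)
    assert prof.mean_pi[0] == pytest.approx(0.3)
    assert prof.weight[0] == 2
    assert prof.weight[1] == 1  # short gene drops out at rank 1
    # weight bookkeeping: total weight equals retained (gene, rank) pairs
    assert prof.weight.sum() == 3


def test_species_mean_profile_rejects_all_empty():
    with pytest.raises(ValueError):
        species_mean_profile([[], []])


def test_profile_tsv_roundtrip(tmp_path):
    prof = species_mean_profile([[(0, 0.2), (1, 0.1)]], species_id="sp1")
    path = tmp_path / "p.tsv"
    prof.write_tsv(path)
    back = diversity.DiversityProfile.read_tsv(path, species_id="sp1")
    np.testing.assert_allclose(back.mean_pi, prof.mean_pi)
    np.testing.assert_array_equal(back.positions, prof.positions)


def test_constant_diversity_profile_is_flat_within_error(rng):
    """Columns generated at constant expected pi yield a flat profile."""
    from divlen import synth

    spec = synth.SynthSpec(
        n_strains=20, n_genes=300, d_min=0.02, d_max=0.02, c=0.01, seed=9
    )
    alns, _ = synth.synth_alignment_set(spec)
    profs = [gene_silent_profile(a) for a in alns]
    prof = species_mean_profile(profs, max_sites=100)
    # binomial-style error bound on each positional mean
    se = np.sqrt(0.02 * 0.07 / prof.weight)  # Var(pi at a site) <~ pi * pi_max_gap
    assert np.all(np.abs(prof.mean_pi - 0.02) < 5 * se + 0.01)
    assert abs(prof.mean_pi.mean() - 0.02) < 0.002


# ---------------------------------------------------------------------------
# diversity vs length
# ---------------------------------------------------------------------------


def test_diversity_length_monotone_set_gives_rho_one():
    alns = []
    for k, (n_codons, pi_minor) in enumerate([(6, 0), (10, 1), (14, 2), (18, 3)]):
        # longer genes get more polymorphic sites -> strictly higher mean pi
        rows = [[], [], [], []]
        for i in range(4):
            rows[i].append("ATG")
        for c in range(n_codons):
            minor = c < pi_minor
            for i in range(4):
                rows[i].append("GGC" if (minor and i == 0) else "GGA")
        alns.append(_aln(["".join(r) for r in rows], gene_id=f"g{k}"))
    table, rho, p = gene_diversity_vs_length(alns)
    assert rho == pytest.approx(1.0)


def test_diversity_length_too_few_genes_is_nan():
    rows = ["ATGGGA"] * 3
    table, rho, p = gene_diversity_vs_length([_aln(rows)])
    assert np.isnan(rho)


# ---------------------------------------------------------------------------
# strain/gene filters
# ---------------------------------------------------------------------------


def test_jaccard_dereplicate_examples():
    # identical sets collapse to one strain
    assert jaccard_dereplicate({"a": {1, 2}, "b": {1, 2}}) == ["a"]
    # d_j = 1 - 1/3 = 0.667 >= 0.01: both retained
    assert jaccard_dereplicate({"a": {"x", "y"}, "b": {"x", "z"}}) == ["a", "b"]
    # three pairwise-identical sets -> 1 retained
    assert jaccard_dereplicate({"a": {1}, "b": {1}, "c": {1}}) == ["a"]


def test_jaccard_dereplicate_retained_pairwise_distant():
    sets = {f"s{i}": set(range(i, i + 50)) for i in range(0, 100, 10)}
    kept = jaccard_dereplicate(sets, min_dist=0.15)
    for a in kept:
        for b in kept:
            if a != b:
                assert diversity.jaccard_distance(sets[a], sets[b]) >= 0.15


def test_jaccard_dereplicate_empty_input_errors():
    with pytest.raises(ValueError):
        jaccard_dereplicate({})


def test_filter_orthologs_rules():
    long = pd.DataFrame(
        {
            "gene_id": ["core"] * 4 + ["rare"] * 2 + ["dup"] * 4,
            "strain_id": ["s1", "s2", "s3", "s4"] * 1 + ["s1", "s2"] + ["s1", "s2", "s3", "s4"],
            "copy_number": [1, 1, 1, 1, 1, 1, 2, 1, 1, 1],
        }
    )
    table = OrthologTable.from_long(long)
    kept = filter_orthologs(table, min_presence=0.75)
    assert kept == ["core"]  # rare fails 75% presence; dup fails single-copy


def test_filter_orthologs_bad_presence():
    table = OrthologTable.from_long(
        pd.DataFrame({"gene_id": ["g"], "strain_id": ["s"], "copy_number": [1]})
    )
    with pytest.raises(ValueError):
        filter_orthologs(table, min_presence=1.5)
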