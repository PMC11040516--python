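"""Wright-Fisher simulator: layout, dynamics, and closed-form conversions."""

import math

import numpy as np
import pandas as pd
import pytest

from divlen import wfsim
from divlen.wfsim import (
    SimConfig,
    alignment_site_pi,
    build_layout,
    default_parameter_table,
    draw_gene_lengths,
    estimate_Ne,
    expected_het_reduction,
    init_population,
    invert_selection,
    run_simulation,
    sample_parameters,
    step_generation,
)


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------


def test_gene_length_distribution(rng):
    lengths = draw_gene_lengths(10_000, rng)
    med = np.median(lengths)
    assert abs(med - 1000) / 1000 < 0.03
    frac = np.mean((lengths >= 450) & (lengths <= 2200))
    assert frac >= 0.93


def test_layout_genes_nonoverlapping_within_chromosome():
    cfg = SimConfig(N=10, generations=1, mu=1e-6, chromosome_length=30_000, seed=3, sample_size=5)
    layout = build_layout(cfg)
    prev_end = 0
    for g in sorted(layout.genes, key=lambda g: g.start):
        assert g.start >= prev_end
        assert g.end <= cfg.chromosome_length
        assert 1 <= g.sel_length <= g.length
        prev_end = g.end


def test_layout_zero_sd_selection_regions():
    cfg = SimConfig(N=10, generations=1, mu=1e-6, L_s_mean=60, L_s_sd=0, seed=1, sample_size=5)
    layout = build_layout(cfg)
    assert all(g.sel_length == 60 for g in layout.genes)


def test_layout_deterministic_under_seed():
    cfg = SimConfig(N=10, generations=1, mu=1e-6, seed=42, sample_size=5)
    assert build_layout(cfg) == build_layout(cfg)


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------


def _tiny_config(**kw):
    defaults = dict(
        N=50, generations=10, mu=1e-5, r_over_m=0.0, chromosome_length=2000,
        sample_size=10, seed=0, L_s_mean=30, L_s_sd=0,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


def test_no_mutation_no_recombination_only_drift():
    cfg = _tiny_config(mu=0.0)
    rng = np.random.default_rng(0)
    pop = init_population(cfg, rng)
    layout = build_layout(cfg, rng)
    for _ in range(20):
        pop = step_generation(pop, cfg, layout, rng)
    # no new alleles can appear: everyone still equals the founder
    assert np.all(pop.genomes == pop.reference)


def test_lethal_selection_never_carries_region_mutations():
    cfg = _tiny_config(s=-1.0, mu=5e-4, generations=30)
    rng = np.random.default_rng(1)
    pop = init_population(cfg, rng)
    layout = build_layout(cfg, rng)
    sel = np.flatnonzero(layout.selection_mask())
    for _ in range(30):
        pop = step_generation(pop, cfg, layout, rng)
        # reproducing individuals never carry a selected-region mutation
        carriers = (pop.genomes[:, sel] != pop.reference[sel]).any(axis=1)
        child = step_generation(pop, cfg, layout, np.random.default_rng(99))
        # all parents of the next generation are mutation-free in the region
        assert not carriers.all()


def test_determinism_identical_seed_identical_sample():
    cfg = _tiny_config(mu=1e-4, r_over_m=1.0, generations=50, seed=7)
    r1 = run_simulation(cfg)
    r2 = run_simulation(cfg)
    assert np.array_equal(r1.sample, r2.sample)
    assert r1.layout == r2.layout


def test_neutral_offspring_distribution_is_wright_fisher(rng):
    """One-generation drift oracle: offspring counts of a neutral allele are
    Binomial(N, p); checked via the variance p(1-p)/N over many one-step runs."""
    N = 100
    cfg = SimConfig(N=N, generations=1, mu=0.0, r_over_m=0.0,
                    chromosome_length=3000, sample_size=10, seed=0)
    layout = build_layout(cfg, np.random.default_rng(0))
    p0 = 0.3
    freqs = []
    for rep in range(400):
        pop = init_population(cfg, np.random.default_rng(rep))
        # plant a biallelic site at frequency p0
        carriers = np.arange(int(p0 * N))
        pop.genomes[carriers, 0] = (pop.reference[0] + 1) % 4
        stepped = step_generation(pop, cfg, layout, np.random.default_rng(1000 + rep))
        freqs.append(np.mean(stepped.genomes[:, 0] != pop.reference[0]))
    freqs = np.array(freqs)
    assert freqs.mean() == pytest.approx(p0, abs=0.01)
    expected_var = p0 * (1 - p0) / N
    # chi-square-ish bound: sample variance within 25% of binomial expectation
    assert abs(freqs.var(ddof=1) - expected_var) / expected_var < 0.25


def test_selection_monotonicity_in_region_diversity():
    """Stronger purifying selection yields lower diversity inside regions."""
    levels = [0.0, -0.01, -0.04, -0.15, -0.6]
    means = []
    for s in levels:
        level_pis = []
        for seed in (11, 12, 13):
            cfg = SimConfig(N=100, generations=400, mu=2.5e-5, r_over_m=0.0,
                            chromosome_length=6000, sample_size=30, s=s,
                            L_s_mean=400, L_s_sd=0, seed=seed)
            res = run_simulation(cfg)
            sel = res.layout.selection_mask()
            level_pis.append(res.site_pi[sel].mean())
        means.append(np.mean(level_pis))
    # non-increasing in |s| up to small stochastic wiggle: rank correlation
    from scipy.stats import spearmanr

    rho, _ = spearmanr(np.abs(levels), means)
    assert rho < -0.8


def test_linked_neutral_diversity_reduced_and_restored_by_recombination():
    """Background selection: with no recombination, purifying selection drags
    down diversity at linked neutral sites genome-wide; recombination
    decouples neutral sites and shrinks the deficit."""

    def neutral_pi(s, rm):
        vals = []
        for seed in (13, 14, 15):
            cfg = SimConfig(N=150, generations=600, mu=2e-5, r_over_m=rm,
                            mean_tract=300, chromosome_length=8000, sample_size=40,
                            s=s, L_s_mean=600, L_s_sd=0, gene_spacing=100,
                            seed=seed)
            res = run_simulation(cfg)
            neutral = ~res.layout.selection_mask()
            vals.append(res.site_pi[neutral].mean())
        return np.mean(vals)

    pi_neutral_run = neutral_pi(0.0, 0.0)
    pi_bgs_linked = neutral_pi(-0.03, 0.0)
    pi_bgs_recomb = neutral_pi(-0.03, 10.0)
    assert pi_bgs_linked < 0.8 * pi_neutral_run  # linked reduction
    assert pi_bgs_recomb > pi_bgs_linked  # deficit shrinks with r/m


def test_sample_site_pi_matches_site_diversity_formula(rng):
    from divlen.diversity import site_diversity

    sample = rng.integers(0, 4, size=(12, 30))
    pis = alignment_site_pi(sample)
    for j in range(30):
        counts = [int((sample[:, j] == b).sum()) for b in range(4)]
        assert pis[j] == pytest.approx(site_diversity(counts), abs=1e-12)


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------


def test_het_reduction_limit_and_values():
    assert expected_het_reduction(0.0) == 1.0
    assert expected_het_reduction(-1e-9) == pytest.approx(1.0, abs=1e-6)
    assert expected_het_reduction(-2.0) == pytest.approx(0.68697, abs=5e-5)
    # strong-selection asymptote 2/|S|
    assert expected_het_reduction(-50.0) == pytest.approx(2 / 50, rel=0.02)
    assert expected_het_reduction(-1e4) == pytest.approx(2e-4, rel=1e-3)


def test_het_reduction_strictly_decreasing_in_strength():
    S = -np.logspace(-2, 2, 30)
    vals = [expected_het_reduction(s) for s in S]
    assert all(a > b for a, b in zip(vals, vals[1:]))


def test_invert_selection_round_trip():
    N_e = 5000
    for s in (-1e-2, -1e-3, -1e-4, -1e-5):
        ratio = expected_het_reduction(2 * N_e * s)
        s_back = invert_selection(ratio, N_e)
        assert abs(s_back - s) < 1e-8


def test_invert_selection_edges():
    assert invert_selection(1.0, 5000) == 0.0
    with pytest.raises(ValueError):
        invert_selection(1.2, 5000)
    s = invert_selection(expected_het_reduction(-2.0), 5000)
    assert s == pytest.approx(-2.0 / 10000, rel=1e-6)


def test_estimate_Ne():
    assert estimate_Ne(0.01, 1e-6) == pytest.approx(5000.0)
    assert estimate_Ne(0.02, 1e-6) == pytest.approx(10000.0)
    with pytest.raises(ValueError):
        estimate_Ne(0.01, 0.0)


# ---------------------------------------------------------------------------
# parameter sampling
# ---------------------------------------------------------------------------


def test_sample_parameters_single_row_identical():
    table = pd.DataFrame(
        {"pi_s": [0.01], "r_over_m": [1.0], "mean_tract": [500.0],
         "S_scaled": [-10.0], "L_s": [76.0]}
    )
    configs = sample_parameters(table, 5, seed=0, N=500)
    assert len(configs) == 5
    assert len({(c.mu, c.r_over_m, c.s, c.L_s_mean) for c in configs}) == 1
    assert configs[0].mu == pytest.approx(0.01 / (2 * 500))


def test_sample_parameters_reproducible_and_purifying():
    table = default_parameter_table(n=30, seed=2)
    c1 = sample_parameters(table, 100, seed=5)
    c2 = sample_parameters(table, 100, seed=5)
    assert len(c1) == 100
    assert [c.seed for c in c1] == [c.seed for c in c2]
    assert all(c.s <= 0 for c in c1)


def test_sample_parameters_empty_table_errors():
    with pytest.raises(ValueError):
        sample_parameters(pd.DataFrame(), 5)
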