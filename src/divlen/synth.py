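"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators cover the analysis surface:

* multi-strain codon alignments whose per-silent-site expected diversity
  follows a chosen asymptotic-regression curve (biallelic sites, minor-allele
  counts solved from the pi formula, randomized between the two bracketing
  integers so expectations match exactly);
* per-gene unpaired-probability windows around the start codon with a
  positive accessibility bump that decays to a flank baseline;
* a pure-birth species tree with Brownian-motion trait data at a known
  Pagel's lambda.

Every generator is deterministic under a fixed seed and records its truth
parameters in a sidecar dict (written as JSON when an output directory is
given), so recovery tests can compare estimates against the generating
values.

Strain relatedness is deliberately not modeled in the alignment generator
(columns are independent): the downstream asymptotic regression consumes only
per-position means and gene-count weights, for which independent columns are
sufficient.  Coalescent-realistic linkage comes from the Wright-Fisher
simulator instead.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, asdict, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .diversity import CodonAlignment
from .structure import POSITIONS, FLANKS, UnpairedProfile
from .wfsim import GENE_LEN_LOG_MEDIAN, GENE_LEN_LOG_SD

#: Codon prefixes whose third position is 4-fold degenerate (standard code).
FOURFOLD_PREFIXES = ("GG", "GC", "CC", "GT", "AC", "TC", "CG", "CT")
BASES = ("A", "C", "G", "T")


@dataclass
class SynthSpec:
    """Parameters of one synthetic species (alignments + structure + tree)."""

    n_strains: int = 30
    n_genes: int = 500
    # ASR truth for the silent-site diversity curve
    d_min: float = 0.002
    d_max: float = 0.010
    c: float = 0.01
    # accessibility-bump truth
    bump_height: float = 0.3
    bump_width: float = 20.0
    bump_peak: int = 10
    flank_sd: float = 0.02
    gene_noise_sd: float = 0.05
    n_structure_genes: int = 400
    # phylogeny truth
    n_tips: int = 50
    lambda_true: float = 1.0
    seed: int = 0

    def truth(self) -> dict:
        return asdict(self)


def expected_pi_curve(spec: SynthSpec, positions: np.ndarray) -> np.ndarray:
    l = np.asarray(positions, float)
    return spec.d_max + (spec.d_min - spec.d_max) * np.exp(-spec.c * l)


def _minor_count_for_pi(target: float, n: int, rng: np.random.Generator) -> int:
    """Minor-allele count whose biallelic pi matches ``target`` in expectation.

    pi(m) = 2 m (n - m) / (n (n - 1)) is solved for real m; the result is
    randomized between the two bracketing integers with probabilities chosen
    so E[pi] equals the target exactly.
    """
    pi_max = 2 * (n // 2) * (n - n // 2) / (n * (n - 1))
    if target > pi_max + 1e-12:
        raise ValueError(f"target pi {target} unattainable with {n} strains")
    if target <= 0:
        return 0
    disc = n * n - 2.0 * target * n * (n - 1)
    m_real = (n - math.sqrt(max(disc, 0.0))) / 2.0
    m0 = math.floor(m_real)
    m1 = m0 + 1

    def pi_of(m: int) -> float:
        return 2.0 * m * (n - m) / (n * (n - 1))

    if m1 > n // 2:
        return m0
    p0, p1 = pi_of(m0), pi_of(m1)
    if p1 == p0:
        return m0
    prob_up = (target - p0) / (p1 - p0)
    return m1 if rng.random() < min(max(prob_up, 0.0), 1.0) else m0


def synth_alignment_set(
    spec: SynthSpec, out_dir: str | Path | None = None
) -> tuple[list[CodonAlignment], dict]:
    """Codon alignments whose silent-site diversity follows the ASR truth.

    Every codon after the start codon comes from a 4-fold family, so silent
    rank l corresponds to codon index l+1.  At rank l a biallelic third-
    position configuration with E[pi] = pi_curve(l) is drawn; first and
    second codon positions are monomorphic.
    """
    if spec.d_min > spec.d_max:
        raise ValueError("d_min must be <= d_max")
    if spec.n_strains < 2:
        raise ValueError("need >=2 strains")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_strains
    strain_ids = tuple(f"s{i:03d}" for i in range(n))
    lengths_bp = np.round(
        rng.lognormal(GENE_LEN_LOG_MEDIAN, GENE_LEN_LOG_SD, size=spec.n_genes)
    ).astype(int)
    n_codons = np.maximum(lengths_bp // 3, 5)

    alignments: list[CodonAlignment] = []
    for g in range(spec.n_genes):
        nc = int(n_codons[g])
        n_silent = nc - 1  # all codons after ATG are 4-fold
        targets = expected_pi_curve(spec, np.arange(n_silent))
        prefix_idx = rng.integers(0, len(FOURFOLD_PREFIXES), size=n_silent)
        major_idx = rng.integers(0, 4, size=n_silent)
        rows = [["ATG"] for _ in range(n)]
        for l in range(n_silent):
            prefix = FOURFOLD_PREFIXES[prefix_idx[l]]
            major = BASES[major_idx[l]]
            minor = BASES[(major_idx[l] + 1 + rng.integers(0, 3)) % 4]
            m = _minor_count_for_pi(float(targets[l]), n, rng)
            carriers = set(rng.choice(n, size=m, replace=False)) if m else set()
            for i in range(n):
                rows[i].append(prefix + (minor if i in carriers else major))
        alignments.append(
            CodonAlignment(
                gene_id=f"gene{g:05d}",
                strain_ids=strain_ids,
                rows=tuple("".join(r) for r in rows),
            )
        )

    truth = {
        "kind": "alignments",
        "d_min": spec.d_min,
        "d_max": spec.d_max,
        "c": spec.c,
        "L_e": math.log(2) / spec.c,
        "S_e": math.log2(spec.d_max / spec.d_min) if spec.d_min > 0 else None,
        "n_strains": n,
        "n_genes": spec.n_genes,
        "seed": spec.seed,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        gene_dir = out_dir / "genes"
        gene_dir.mkdir(parents=True, exist_ok=True)
        for aln in alignments:
            with open(gene_dir / f"{aln.gene_id}.fasta", "w") as fh:
                for sid, row in zip(aln.strain_ids, aln.rows):
                    fh.write(f">{sid}\n{row}\n")
        (out_dir / "truth.json").write_text(json.dumps(truth, indent=2))
    return alignments, truth


# ---------------------------------------------------------------------------
# accessibility profiles
# ---------------------------------------------------------------------------


def _bump_curve(spec: SynthSpec, half_width_sds: float = 2.5) -> tuple[np.ndarray, int]:
    """Truncated-Gaussian accessibility bump that reaches exactly zero at the
    edge of its support (peak + half_width_sds * width), giving the generator
    a well-defined truth zero crossing."""
    pos = POSITIONS.astype(float)
    lo = spec.bump_peak - half_width_sds * spec.bump_width
    hi = spec.bump_peak + half_width_sds * spec.bump_width
    raw = np.exp(-((pos - spec.bump_peak) ** 2) / (2.0 * spec.bump_width**2))
    edge = math.exp(-(half_width_sds**2) / 2.0)
    bump = np.where((pos >= lo) & (pos <= hi), (raw - edge) / (1.0 - edge), 0.0)
    bump = np.clip(bump, 0.0, None) * spec.bump_height
    return bump, int(round(hi))


def synth_unpaired_profiles(
    spec: SynthSpec, out_dir: str | Path | None = None
) -> tuple[list[UnpairedProfile], dict]:
    """Per-gene unpaired-probability windows with a known bump truth.

    The species-level curve is baseline + truncated-Gaussian bump + a fixed
    positional flank pattern (drawn once, standardized to sd ``flank_sd``
    over the flank union, zero inside the bump support).  Per-gene noise of
    sd ``gene_noise_sd`` is added on top and averages out across genes; the
    flank pattern is what the z-score baseline measures.
    """
    rng = np.random.default_rng(spec.seed + 1)
    baseline = 0.5
    bump, zero_cross = _bump_curve(spec)
    flank_idx = np.concatenate(
        [np.flatnonzero((POSITIONS >= lo) & (POSITIONS <= hi)) for lo, hi in FLANKS]
    )
    pattern = rng.normal(0.0, 1.0, size=len(POSITIONS))
    pattern[bump > 0] = 0.0
    fp = pattern[flank_idx]
    pattern = (pattern - fp.mean()) * (spec.flank_sd / fp.std(ddof=0))
    pattern[bump > 0] = 0.0
    species_curve = np.clip(baseline + bump + pattern, 0.0, 1.0)

    profiles = []
    for g in range(spec.n_structure_genes):
        noise = rng.normal(0.0, spec.gene_noise_sd, size=len(POSITIONS))
        p = np.clip(species_curve + noise, 0.0, 1.0)
        profiles.append(UnpairedProfile(f"gene{g:05d}", p))

    # truth L_ss: first position >= +5 at which the noiseless species curve
    # falls to or below the flank baseline
    flank_mean = float(species_curve[flank_idx].mean())
    tail = POSITIONS >= 5
    below = tail & (species_curve - flank_mean <= 1e-12)
    truth = {
        "kind": "unpaired_profiles",
        "bump_height": spec.bump_height,
        "bump_width": spec.bump_width,
        "bump_peak": spec.bump_peak,
        "flank_sd": spec.flank_sd,
        "S_ss": spec.bump_height / spec.flank_sd,
        "L_ss": int(POSITIONS[below][0]) if below.any() else None,
        "zero_cross": zero_cross,
        "n_genes": spec.n_structure_genes,
        "seed": spec.seed,
    }
    if out_dir is not None:
        from .structure import write_unpaired_tsv

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_unpaired_tsv(profiles, out_dir / "unpaired.tsv")
        (out_dir / "truth.json").write_text(json.dumps(truth, indent=2))
    return profiles, truth


# ---------------------------------------------------------------------------
# phylogeny + traits
# ---------------------------------------------------------------------------


def synth_phylo_traits(
    n_tips: int = 50,
    lambda_true: float = 1.0,
    beta: np.ndarray | list[float] = (0.5,),
    sigma_bm: float = 1.0,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[dendropy.Tree, pd.DataFrame, dict]:
    """Pure-birth tree plus traits: response = X beta + noise with covariance
    sigma_bm^2 * C(lambda_true), predictors iid standard normal per tip."""
    beta = np.asarray(beta, float)
    pyrng = random.Random(seed)
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=pyrng,
    )
    # the sampler stops exactly at the n-th speciation, leaving zero-length
    # terminal branches (a singular covariance); extend all tips by the
    # waiting time to the next, unrealized event to keep the tree ultrametric
    extra = pyrng.expovariate(float(n_tips))
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
        leaf.taxon.label = f"sp{i:03d}"
    taxa = [t.label for t in tree.taxon_namespace]

    from .compstats import tree_vcv, _lambda_cov

    C = tree_vcv(tree, taxa)
    V = _lambda_cov(C, lambda_true) * sigma_bm**2
    V[np.diag_indices_from(V)] *= 1.0 + 1e-9
    rng = np.random.default_rng(seed + 17)
    X = rng.normal(size=(n_tips, len(beta)))
    L = np.linalg.cholesky(V)
    noise = L @ rng.normal(size=n_tips)
    y = X @ beta + noise
    traits = pd.DataFrame(
        X, columns=[f"x{j}" for j in range(len(beta))], index=taxa
    )
    traits["y"] = y
    truth = {
        "kind": "phylo_traits",
        "lambda": lambda_true,
        "beta": beta.tolist(),
        "sigma_bm": sigma_bm,
        "n_tips": n_tips,
        "seed": seed,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        tree.write(path=str(out_dir / "tree.nwk"), schema="newick")
        traits.rename_axis("species_id").to_csv(out_dir / "traits.tsv", sep="\t")
        (out_dir / "truth.json").write_text(json.dumps(truth, indent=2))
    return tree, traits, truth
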