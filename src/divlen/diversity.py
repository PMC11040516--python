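"""Per-site synonymous nucleotide diversity from codon alignments.

Nucleotide diversity (π) at a site is the average pairwise difference among
the sequences sampled from a population.  Because purifying selection near
translation initiation depresses π at the 5'-end of genes, this module
profiles π over 4-fold degenerate ("silent") sites indexed by their rank from
the start codon, averaging across the single-copy core genes of a species.

The filtering rules mirror standard practice for multi-strain bacterial
panels: near-identical strains are dereplicated by Jaccard distance between
their protein-id sets, orthologs must be single-copy and present in a minimum
fraction of strains, gappy alignment columns are excluded, and degeneracy is
read off a consensus sequence under the standard genetic code.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
#: Characters treated as missing for consensus and diversity counting.
GAP_CHARS = frozenset({"-", "N", "n", ".", "?"})

_STANDARD_TABLE = unambiguous_dna_by_id[1]


def _codon_aa(codon: str) -> str:
    """Amino acid (or '*') encoded by an unambiguous codon, standard code."""
    if codon in _STANDARD_TABLE.stop_codons:
        return "*"
    return _STANDARD_TABLE.forward_table[codon]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CodonAlignment:
    """In-frame, gapped nucleotide alignment of one gene across strains."""

    gene_id: str
    strain_ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError(f"{self.gene_id}: need >=2 rows, got {len(self.rows)}")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"{self.gene_id}: rows have unequal lengths {lengths}")
        (length,) = lengths
        if length % 3 != 0:
            raise ValueError(f"{self.gene_id}: length {length} not divisible by 3")
        if len(self.strain_ids) != len(self.rows):
            raise ValueError(f"{self.gene_id}: strain/row count mismatch")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_strains(self) -> int:
        return len(self.rows)

    def column(self, i: int) -> str:
        return "".join(r[i] for r in self.rows)


#: Sentinel degeneracy codes.
EXCLUDED = -1
AMBIGUOUS = 0


@dataclass
class SiteClassification:
    """Per-column consensus, gap fraction and degeneracy fold of an alignment.

    ``degeneracy[i]`` is 1/2/3/4 where a consensus codon exists, ``AMBIGUOUS``
    (0) where no base reaches the consensus threshold (or the codon is
    incomplete), and ``EXCLUDED`` (-1) where the column exceeds the gap
    threshold.
    """

    consensus: list[str | None]
    gap_fraction: np.ndarray
    degeneracy: np.ndarray

    def __len__(self) -> int:
        return len(self.consensus)


@dataclass
class DiversityProfile:
    """Mean silent-site diversity by position for one (real or simulated) species.

    ``positions`` are 0-based silent-site ranks from the translation start
    (or bp offsets in bp mode); ``weight`` counts the genes contributing at
    each position and serves as the regression weight downstream.
    """

    species_id: str
    positions: np.ndarray
    mean_pi: np.ndarray
    weight: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.mean_pi = np.asarray(self.mean_pi, dtype=float)
        self.weight = np.asarray(self.weight, dtype=float)
        if not (len(self.positions) == len(self.mean_pi) == len(self.weight)):
            raise ValueError("profile arrays must be equal length")
        if len(self.weight) and self.weight.min() < 1:
            raise ValueError("every stored position needs weight >= 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": self.positions, "mean_pi": self.mean_pi, "n_genes": self.weight}
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path, species_id: str | None = None) -> "DiversityProfile":
        df = pd.read_csv(path, sep="\t")
        return cls(
            species_id=species_id or Path(path).stem,
            positions=df["position"].to_numpy(),
            mean_pi=df["mean_pi"].to_numpy(),
            weight=df["n_genes"].to_numpy(),
        )


@dataclass
class OrthologTable:
    """Gene x strain copy-number matrix (0 = absent)."""

    copy_number: pd.DataFrame  # index: gene_id, columns: strain_id

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "OrthologTable":
        """Build from a long table with columns gene_id, strain_id, copy_number."""
        wide = (
            df.pivot_table(
                index="gene_id", columns="strain_id", values="copy_number", fill_value=0
            )
            .astype(int)
        )
        return cls(wide)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "OrthologTable":
        return cls.from_long(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# strain and gene filtering
# ---------------------------------------------------------------------------


def jaccard_distance(a: set, b: set) -> float:
    union = len(a | b)
    if union == 0:
        raise ValueError("both sets empty")
    return 1.0 - len(a & b) / union


def jaccard_dereplicate(
    protein_sets: Mapping[str, set], min_dist: float = 0.01
) -> list[str]:
    """Greedily retain strains whose protein-id sets are pairwise >= ``min_dist`` apart.

    Strains are scanned in input order; a strain is kept only if its Jaccard
    distance to every already-retained strain is at least ``min_dist``.
    Deterministic for a given input order.
    """
    if not protein_sets:
        raise ValueError("no strains given")
    retained: list[str] = []
    for strain, prots in protein_sets.items():
        if not prots:
            raise ValueError(f"strain {strain} has an empty protein set")
        if all(jaccard_distance(prots, protein_sets[r]) >= min_dist for r in retained):
            retained.append(strain)
    return retained


def filter_orthologs(table: OrthologTable, min_presence: float = 0.75) -> list[str]:
    """Genes that are single-copy everywhere and present in >= ``min_presence`` of strains."""
    if not 0 < min_presence <= 1:
        raise ValueError(f"min_presence must be in (0, 1], got {min_presence}")
    cn = table.copy_number
    if cn.empty:
        raise ValueError("empty ortholog table")
    single = (cn <= 1).all(axis=1)
    presence = (cn >= 1).mean(axis=1) >= min_presence
    return list(cn.index[single & presence])


# ---------------------------------------------------------------------------
# site classification and diversity
# ---------------------------------------------------------------------------


def _column_consensus(
    column: Sequence[str], consensus_threshold: float
) -> tuple[str | None, float]:
    """(consensus base or None, gap fraction); the modal-base fraction uses all rows."""
    n = len(column)
    counts = Counter(c.upper() for c in column)
    n_gap = sum(counts.get(g, 0) for g in ("-", "N", ".", "?"))
    base_counts = {b: counts.get(b, 0) for b in BASES}
    best = max(base_counts, key=base_counts.get)  # ties: fixed A<C<G<T order
    if base_counts[best] / n >= consensus_threshold and base_counts[best] > 0:
        return best, n_gap / n
    return None, n_gap / n


def _third_position_degeneracy(codon: str) -> int:
    """Number of third-position bases preserving the amino acid of ``codon``."""
    aa = _codon_aa(codon)
    return sum(1 for b in BASES if _codon_aa(codon[:2] + b) == aa)


def classify_sites(
    aln: CodonAlignment,
    consensus_threshold: float = 0.6,
    max_gap_frac: float = 0.7,
) -> SiteClassification:
    """Consensus, gap fraction and degeneracy fold for every alignment column.

    Degeneracy at a column is read from the standard genetic code applied to
    the consensus codon containing it; columns whose codon has any
    no-consensus position get ``AMBIGUOUS``, over-gapped columns ``EXCLUDED``.
    """
    length = aln.length
    consensus: list[str | None] = [None] * length
    gap_fraction = np.zeros(length)
    degeneracy = np.full(length, AMBIGUOUS, dtype=int)

    for i in range(length):
        consensus[i], gap_fraction[i] = _column_consensus(aln.column(i), consensus_threshold)

    for codon_start in range(0, length, 3):
        triplet = consensus[codon_start : codon_start + 3]
        if any(b is None for b in triplet):
            continue
        codon = "".join(triplet)  # type: ignore[arg-type]
        # Degeneracy per position within the codon.
        aa = _codon_aa(codon)
        for offset in range(3):
            fold = sum(
                1
                for b in BASES
                if _codon_aa(codon[:offset] + b + codon[offset + 1 :]) == aa
            )
            degeneracy[codon_start + offset] = fold

    degeneracy[gap_fraction > max_gap_frac] = EXCLUDED
    return SiteClassification(consensus, gap_fraction, degeneracy)


def site_diversity(base_counts: Mapping[str, int] | Sequence[int]) -> float:
    """π at one site: 2·Σ_{i<j} f_i f_j / (N(N−1)) over the four base counts.

    Equals the mean of the "bases differ" indicator over all N(N−1)/2
    sequence pairs.  Gaps/N must be removed before counting; N < 2 is
    undefined and raises.
    """
    if isinstance(base_counts, Mapping):
        f = np.array([base_counts.get(b, 0) for b in BASES], dtype=float)
    else:
        f = np.asarray(base_counts, dtype=float)
    n = f.sum()
    if n < 2:
        raise ValueError("site diversity undefined for fewer than 2 sequences")
    pair_same = (f * (f - 1)).sum()
    return float(1.0 - pair_same / (n * (n - 1)))


def _column_base_counts(column: str) -> dict[str, int]:
    counts = Counter(column.upper())
    return {b: counts.get(b, 0) for b in BASES}


def gene_silent_profile(
    aln: CodonAlignment,
    classes: SiteClassification | None = None,
    *,
    consensus_threshold: float = 0.6,
    max_gap_frac: float = 0.7,
    position_mode: str = "silent_rank",
) -> list[tuple[int, float]]:
    """(position, π) over the gene's eligible 4-fold degenerate sites.

    Eligible sites are third codon positions that are 4-fold degenerate on the
    consensus, not gap-excluded, and carry >= 2 ungapped bases.  In
    ``silent_rank`` mode (default) positions are the 0-based rank of eligible
    sites in genomic order — excluded columns do not occupy a rank; in ``bp``
    mode positions are the bp offset of the column from the translation start.
    """
    if position_mode not in ("silent_rank", "bp"):
        raise ValueError(f"unknown position_mode {position_mode!r}")
    if classes is None:
        classes = classify_sites(aln, consensus_threshold, max_gap_frac)
    out: list[tuple[int, float]] = []
    rank = 0
    for col in range(2, aln.length, 3):
        if classes.degeneracy[col] != 4:
            continue
        counts = _column_base_counts(aln.column(col))
        n = sum(counts.values())
        if n < 2:
            logger.debug("%s: column %d skipped, <2 ungapped bases", aln.gene_id, col)
            continue
        pos = rank if position_mode == "silent_rank" else col
        out.append((pos, site_diversity(counts)))
        rank += 1
    return out


def species_mean_profile(
    gene_profiles: Iterable[Sequence[tuple[int, float]]],
    max_sites: int = 500,
    species_id: str = "species",
) -> DiversityProfile:
    """Average gene profiles by position, weighting each position by its gene count."""
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    n_nonempty = 0
    for prof in gene_profiles:
        if not prof:
            continue
        n_nonempty += 1
        for pos, pi in prof:
            if pos >= max_sites:
                continue
            sums[pos] = sums.get(pos, 0.0) + pi
            counts[pos] = counts.get(pos, 0) + 1
    if n_nonempty == 0:
        raise ValueError("no genes with eligible silent sites")
    positions = np.array(sorted(sums), dtype=int)
    mean_pi = np.array([sums[p] / counts[p] for p in positions])
    weight = np.array([counts[p] for p in positions], dtype=float)
    return DiversityProfile(species_id, positions, mean_pi, weight)


def gene_diversity_vs_length(
    alignments: Iterable[CodonAlignment],
    *,
    consensus_threshold: float = 0.6,
    max_gap_frac: float = 0.7,
) -> tuple[pd.DataFrame, float, float]:
    """Per-gene mean silent diversity vs gene length, plus their Spearman ρ.

    Gene length is the alignment length in bp.  Returns (table, rho, p);
    rho/p are NaN with fewer than 3 genes carrying silent sites.
    """
    from .compstats import spearman

    records = []
    for aln in alignments:
        prof = gene_silent_profile(
            aln, consensus_threshold=consensus_threshold, max_gap_frac=max_gap_frac
        )
        mean_pi = float(np.mean([pi for _, pi in prof])) if prof else np.nan
        records.append(
            {
                "gene_id": aln.gene_id,
                "length_bp": aln.length,
                "n_fourfold_sites": len(prof),
                "mean_pi": mean_pi,
            }
        )
    table = pd.DataFrame.from_records(records)
    usable = table.dropna(subset=["mean_pi"])
    if len(usable) < 3:
        return table, float("nan"), float("nan")
    rho, p = spearman(usable["length_bp"].to_numpy(), usable["mean_pi"].to_numpy())
    return table, rho, p


# ---------------------------------------------------------------------------
# file IO
# ---------------------------------------------------------------------------


def read_codon_fasta(path: str | Path, gene_id: str | None = None) -> CodonAlignment:
    """Read one aligned, in-frame FASTA into a CodonAlignment."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise ValueError(f"{path}: need >=2 aligned sequences")
    return CodonAlignment(
        gene_id=gene_id or Path(path).stem,
        strain_ids=tuple(r.id for r in records),
        rows=tuple(str(r.seq).upper() for r in records),
    )


def species_profile_from_dir(
    species_dir: str | Path,
    max_sites: int = 500,
    consensus_threshold: float = 0.6,
    max_gap_frac: float = 0.7,
    position_mode: str = "silent_rank",
) -> DiversityProfile:
    """Profile a species from ``<species_dir>/genes/*.fasta`` codon alignments."""
    species_dir = Path(species_dir)
    gene_dir = species_dir / "genes"
    paths = sorted(gene_dir.glob("*.fasta"))
    if not paths:
        raise FileNotFoundError(f"no gene alignments under {gene_dir}")
    profiles = []
    for p in paths:
        aln = read_codon_fasta(p)
        profiles.append(
            gene_silent_profile(
                aln,
                consensus_threshold=consensus_threshold,
                max_gap_frac=max_gap_frac,
                position_mode=position_mode,
            )
        )
    return species_mean_profile(profiles, max_sites, species_id=species_dir.name)
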