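"""Dataset-level filters, prevalence summaries and enrichment statistics.

Operates on a table of per-structure scan results (one row per crystal
structure: resolution, R-factor, ligand class, protein class, optional
sequence, and the number of sugar monomers engaged in CH−π stacking).

Quality filters keep structures at <= 2.0 Å resolution and <= 0.2 R-factor
(inclusive boundaries).  Redundancy is removed by greedy sequence
clustering at 95% identity.  Enrichment of a trait (e.g. enzyme
annotation) in a subset is tested with a Pearson χ² test on a 2×2 table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats

__all__ = [
    "StructureRecord",
    "Contingency2x2",
    "DatasetSummary",
    "MissingMetadataWarning",
    "ZeroMarginalError",
    "filter_records",
    "cluster_sequences",
    "pairwise_identity",
    "prevalence_summary",
    "chi2_test",
    "sankey_counts",
    "round_half_up",
    "read_metadata_tsv",
    "records_to_frame",
    "analyze_dataset",
]

METADATA_COLUMNS = ["pdb_id", "resolution", "r_factor", "ligand_class",
                    "protein_class", "sequence", "n_stacked_monomers"]


class MissingMetadataWarning(UserWarning):
    """A record lacked resolution or R-factor and was excluded."""


class ZeroMarginalError(ValueError):
    """The χ² statistic is undefined for a table with a zero marginal."""


@dataclass
class StructureRecord:
    """Per-structure metadata plus the stacking scan outcome."""

    pdb_id: str
    resolution: float | None
    r_factor: float | None
    ligand_class: str            # 'monosaccharide' | 'oligosaccharide'
    protein_class: str           # 'enzyme' | 'other'
    n_stacked_monomers: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.resolution is not None and not self.resolution > 0:
            raise ValueError("resolution must be positive")
        if self.r_factor is not None and not (0 <= self.r_factor <= 1):
            raise ValueError("r_factor must be in [0, 1]")
        if self.n_stacked_monomers < 0:
            raise ValueError("n_stacked_monomers must be >= 0")
        if self.ligand_class not in ("monosaccharide", "oligosaccharide"):
            raise ValueError(f"unknown ligand_class {self.ligand_class!r}")


@dataclass(frozen=True)
class Contingency2x2:
    """Counts (a, b; c, d): rows = group/background, cols = trait/no-trait."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("table total must be positive")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class DatasetSummary:
    """Prevalence summary; percentages carry full precision internally."""

    n_total: int
    n_mono: int
    n_oligo: int
    n_stacked_total: int
    n_stacked_mono: int
    n_stacked_oligo: int
    prevalence_total: float      # percent, unrounded
    prevalence_mono: float
    prevalence_oligo: float
    oligo_share: float           # percent of dataset bound to oligosaccharides
    n_multi_stacking: int        # records with >= 2 stacked monomers
    n_clusters: int | None = None  # unique-protein count, when sequences given

    def display(self) -> dict[str, int]:
        """Report percentages rounded half-up to integers."""
        return {
            "prevalence_total_pct": round_half_up(self.prevalence_total),
            "prevalence_mono_pct": round_half_up(self.prevalence_mono),
            "prevalence_oligo_pct": round_half_up(self.prevalence_oligo),
            "oligo_share_pct": round_half_up(self.oligo_share),
        }


def round_half_up(x: float) -> int:
    """Round to nearest integer with exact halves going up (0.5 -> 1)."""
    return int(math.floor(x + 0.5))


def filter_records(records: list[StructureRecord],
                   res_max: float = 2.0,
                   rfac_max: float = 0.2) -> list[StructureRecord]:
    """Keep records with resolution <= res_max and R-factor <= rfac_max.

    Records with missing metadata are excluded with a warning.
    """
    kept: list[StructureRecord] = []
    for rec in records:
        if rec.resolution is None or rec.r_factor is None:
            warnings.warn(f"{rec.pdb_id}: missing resolution/R-factor; excluded",
                          MissingMetadataWarning, stacklevel=2)
            continue
        if rec.resolution <= res_max and rec.r_factor <= rfac_max:
            kept.append(rec)
    return kept


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_identity(a: str, b: str,
                      aligner: Align.PairwiseAligner | None = None) -> float:
    """Global-alignment identity: exact matches / alignment columns.

    Scoring: match +1, mismatch 0, linear gap −1.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if a == b:
        return 1.0
    aligner = aligner or _make_aligner()
    alignment = aligner.align(a, b)[0]
    counts = alignment.counts()
    return counts.identities / alignment.length


def cluster_sequences(sequences: list[str],
                      identity_cut: float = 0.95) -> list[int]:
    """Greedy order-dependent clustering by pairwise sequence identity.

    Sequences are processed in input order; each joins the first existing
    cluster whose *representative* (its founding sequence) has identity
    >= ``identity_cut``, else founds a new cluster.  Returns one cluster
    index per input sequence.
    """
    if not sequences:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner()
    representatives: list[str] = []
    assignments: list[int] = []
    for seq in sequences:
        if not seq:
            raise ValueError("sequences must be non-empty strings")
        placed = False
        for k, rep in enumerate(representatives):
            if pairwise_identity(seq, rep, aligner) >= identity_cut:
                assignments.append(k)
                placed = True
                break
        if not placed:
            assignments.append(len(representatives))
            representatives.append(seq)
    return assignments


def prevalence_summary(records: list[StructureRecord],
                       identity_cut: float = 0.95) -> DatasetSummary:
    """Stacking prevalence per ligand class and pooled.

    A record counts as stacked when ``n_stacked_monomers >= 1``.  When every
    record carries a sequence, a unique-protein cluster count is included.
    """
    if not records:
        raise ValueError("records must be non-empty")
    mono = [r for r in records if r.ligand_class == "monosaccharide"]
    oligo = [r for r in records if r.ligand_class == "oligosaccharide"]
    n_total = len(records)

    def pct(stacked: int, n: int) -> float:
        return 100.0 * stacked / n if n else 0.0

    s_mono = sum(1 for r in mono if r.n_stacked_monomers >= 1)
    s_oligo = sum(1 for r in oligo if r.n_stacked_monomers >= 1)
    n_clusters = None
    if all(r.sequence for r in records):
        n_clusters = max(cluster_sequences([r.sequence for r in records],
                                           identity_cut)) + 1
    return DatasetSummary(
        n_total=n_total,
        n_mono=len(mono),
        n_oligo=len(oligo),
        n_stacked_total=s_mono + s_oligo,
        n_stacked_mono=s_mono,
        n_stacked_oligo=s_oligo,
        prevalence_total=pct(s_mono + s_oligo, n_total),
        prevalence_mono=pct(s_mono, len(mono)),
        prevalence_oligo=pct(s_oligo, len(oligo)),
        oligo_share=pct(len(oligo), n_total),
        n_multi_stacking=sum(1 for r in records if r.n_stacked_monomers >= 2),
        n_clusters=n_clusters,
    )


def chi2_test(table: Contingency2x2,
              correction: bool = False) -> tuple[float, float]:
    """Pearson χ² test of independence on a 2×2 table (df = 1).

    Yates continuity correction is applied only when ``correction`` is set.
    Raises :class:`ZeroMarginalError` when any row or column sums to zero.
    """
    arr = table.as_array()
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ZeroMarginalError("χ² undefined: a marginal of the table is zero")
    chi2, p, dof, _ = stats.chi2_contingency(arr, correction=correction)
    assert dof == 1
    return float(chi2), float(p)


_STACK_CLASSES = ("0", "1", "2+")


def sankey_counts(records: list[StructureRecord]) -> dict[str, dict[str, int]]:
    """Nested counts: ligand class -> stacked-monomer class ('0', '1', '2+').

    Every record lands in exactly one leaf; zero leaves are present, not
    absent, so marginals always reconstruct the total.
    """
    tree = {lig: {cls: 0 for cls in _STACK_CLASSES}
            for lig in ("monosaccharide", "oligosaccharide")}
    for rec in records:
        n = rec.n_stacked_monomers
        cls = "0" if n == 0 else ("1" if n == 1 else "2+")
        tree[rec.ligand_class][cls] += 1
    return tree


# ---------------------------------------------------------------------------
# Table I/O and the dataset pipeline
# ---------------------------------------------------------------------------

def records_to_frame(records: list[StructureRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{c: getattr(r, c) for c in METADATA_COLUMNS} for r in records],
        columns=METADATA_COLUMNS)


def read_metadata_tsv(path) -> list[StructureRecord]:
    """Read a TSV metadata table into records (empty sequence -> None)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns and c != "sequence"]
    if missing:
        raise ValueError(f"metadata table missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        seq = row.get("sequence")
        if isinstance(seq, float) and math.isnan(seq):
            seq = None
        records.append(StructureRecord(
            pdb_id=str(row["pdb_id"]),
            resolution=None if pd.isna(row["resolution"]) else float(row["resolution"]),
            r_factor=None if pd.isna(row["r_factor"]) else float(row["r_factor"]),
            ligand_class=str(row["ligand_class"]),
            protein_class=str(row["protein_class"]),
            n_stacked_monomers=int(row["n_stacked_monomers"]),
            sequence=seq,
        ))
    return records


def enrichment_tables(records: list[StructureRecord],
                      identity_cut: float = 0.95,
                      ) -> dict[str, Contingency2x2]:
    """2×2 enzyme-enrichment tables for the multi-stacking subset.

    Two constructions are reported because the exact marginal choice for
    such a test is a modelling decision:

    * ``structures``: rows = (multi-stacking structures, all other
      structures); cols = (enzyme, other).
    * ``proteins`` (only when all records carry sequences): the same split
      after collapsing structures into unique-protein clusters; a cluster
      is 'multi-stacking' when any member is, and takes the protein class
      of its first member.
    """
    multi = [r for r in records if r.n_stacked_monomers >= 2]
    rest = [r for r in records if r.n_stacked_monomers < 2]
    out = {"structures": Contingency2x2(
        a=sum(1 for r in multi if r.protein_class == "enzyme"),
        b=sum(1 for r in multi if r.protein_class != "enzyme"),
        c=sum(1 for r in rest if r.protein_class == "enzyme"),
        d=sum(1 for r in rest if r.protein_class != "enzyme"),
    )}
    if records and all(r.sequence for r in records):
        labels = cluster_sequences([r.sequence for r in records], identity_cut)
        clusters: dict[int, list[StructureRecord]] = {}
        for lab, rec in zip(labels, records):
            clusters.setdefault(lab, []).append(rec)
        is_enzyme = {k: v[0].protein_class == "enzyme" for k, v in clusters.items()}
        is_multi = {k: any(r.n_stacked_monomers >= 2 for r in v)
                    for k, v in clusters.items()}
        out["proteins"] = Contingency2x2(
            a=sum(1 for k in clusters if is_multi[k] and is_enzyme[k]),
            b=sum(1 for k in clusters if is_multi[k] and not is_enzyme[k]),
            c=sum(1 for k in clusters if not is_multi[k] and is_enzyme[k]),
            d=sum(1 for k in clusters if not is_multi[k] and not is_enzyme[k]),
        )
    return out


def analyze_dataset(records: list[StructureRecord],
                    res_max: float = 2.0,
                    rfac_max: float = 0.2,
                    identity_cut: float = 0.95) -> dict:
    """Filter, summarize and test a metadata table; returns a JSON-able dict."""
    surviving = filter_records(records, res_max=res_max, rfac_max=rfac_max)
    if not surviving:
        raise ValueError("no records survive the quality filters")
    summary = prevalence_summary(surviving, identity_cut=identity_cut)
    result = {
        "n_input": len(records),
        "n_filtered": len(surviving),
        "summary": {
            "n_total": summary.n_total,
            "n_mono": summary.n_mono,
            "n_oligo": summary.n_oligo,
            "n_stacked_total": summary.n_stacked_total,
            "n_stacked_mono": summary.n_stacked_mono,
            "n_stacked_oligo": summary.n_stacked_oligo,
            "n_multi_stacking": summary.n_multi_stacking,
            "n_clusters": summary.n_clusters,
            **summary.display(),
        },
        "sankey": sankey_counts(surviving),
        "enrichment": {},
    }
    for name, table in enrichment_tables(surviving, identity_cut).items():
        try:
            chi2, p = chi2_test(table)
            result["enrichment"][name] = {
                "table": [[table.a, table.b], [table.c, table.d]],
                "chi2": chi2, "p_value": p,
            }
        except ZeroMarginalError:
            result["enrichment"][name] = {
                "table": [[table.a, table.b], [table.c, table.d]],
                "chi2": None, "p_value": None,
            }
    return result
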