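"""PSM tables, protein inference, and balanced spectral counting.

Proteomic stable-isotope-probing (SIP) searches score each tandem mass
spectrum against a sequence database over a grid of candidate ``13C`` atom
enrichments, so every peptide-spectrum match (PSM) carries a percent
enrichment in addition to its peptide, candidate protein group, taxonomic
lineage, and COG functional category.  This module defines the in-memory
model for those tables, the reader/writer for the pipeline's tab-delimited
dialect, the two-peptide protein-identification rule, and balanced spectral
counting (distributing each spectrum's unit count over the proteins that
share its peptide).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Inclusive percent-13C threshold above which a PSM counts as labeled.
#: Natural 13C abundance is 1.109%; enrichment calls at or above 2% are
#: distinguishable from it.
LABEL_THRESHOLD_PCT = 2.0

#: Natural abundance of 13C, percent of carbon atoms.
NATURAL_ABUNDANCE_PCT = 1.109

NA_TOKEN = "NA"

PSM_COLUMNS = [
    "sample_id",
    "spectrum_id",
    "peptide",
    "proteins",
    "enrichment_pct",
    "taxon_order",
    "taxon_genus",
    "cog",
]

PROTEIN_COLUMNS = [
    "sample_id",
    "protein_id",
    "taxon_order",
    "taxon_genus",
    "cog",
    "n_unique_peptides",
    "n_total_peptides",
    "balanced_count",
    "relative_abundance",
]


class PsmFormatError(ValueError):
    """The table does not conform to the PSM TSV dialect (e.g. missing column)."""


class PsmRowError(ValueError):
    """A single row could not be parsed; carries the 1-based file line number."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


@dataclass(frozen=True)
class PsmRecord:
    """One scored spectrum.

    ``protein_ids`` is the ordered protein group the peptide maps to;
    ``balanced_weight`` defaults to 1 (each spectrum is one observation for
    sample-level metrics, regardless of how its count is later distributed
    over proteins).
    """

    sample_id: str
    spectrum_id: str
    peptide: str
    protein_ids: tuple[str, ...]
    enrichment_pct: float
    taxon_order: Optional[str] = None
    taxon_genus: Optional[str] = None
    cog_categories: frozenset[str] = frozenset()
    balanced_weight: float = 1.0
    orphaned: bool = False

    def __post_init__(self) -> None:
        if not self.protein_ids:
            raise ValueError("PsmRecord requires a non-empty protein group")
        if not 0.0 <= self.enrichment_pct <= 100.0:
            raise ValueError(
                f"enrichment_pct {self.enrichment_pct} outside [0, 100]"
            )
        if self.balanced_weight < 0:
            raise ValueError("balanced_weight must be non-negative")

    def is_labeled(self, threshold: float = LABEL_THRESHOLD_PCT) -> bool:
        return self.enrichment_pct >= threshold


@dataclass
class ProteinRecord:
    """A protein (group member) with its supporting peptides and counts."""

    protein_id: str
    peptides_unique: frozenset[str] = frozenset()
    peptides_shared: frozenset[str] = frozenset()
    taxon_order: Optional[str] = None
    taxon_genus: Optional[str] = None
    cog_categories: frozenset[str] = frozenset()
    balanced_count: float = 0.0
    relative_abundance: float = 0.0

    @property
    def identified(self) -> bool:
        """Two-peptide rule: >=1 unique peptide and >=2 distinct peptides."""
        n_unique = len(self.peptides_unique)
        return n_unique >= 1 and n_unique + len(self.peptides_shared) >= 2


@dataclass
class SampleTable:
    """All PSMs and (after filtering) identified proteins of one sample."""

    sample_id: str
    psms: list[PsmRecord]
    proteins: list[ProteinRecord] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)
    unassigned_weight: float = 0.0

    def enrichments(self) -> np.ndarray:
        return np.array([p.enrichment_pct for p in self.psms], dtype=float)

    def weights(self, kind: str = "unit") -> np.ndarray:
        """Per-PSM weights for spectral metrics.

        ``unit``: every PSM counts 1 (the per-spectrum convention).
        ``balanced``: orphaned PSMs (whole protein group unidentified) carry
        weight 0, all others 1 — each assigned spectrum contributes one
        balanced spectral count in total however it is split over proteins.
        """
        if kind == "unit":
            return np.ones(len(self.psms))
        if kind == "balanced":
            return np.array(
                [0.0 if p.orphaned else p.balanced_weight for p in self.psms]
            )
        raise ValueError(f"unknown weight kind {kind!r}")


@dataclass
class PsmParseResult:
    """Parsed sample tables plus any rejected rows."""

    tables: list[SampleTable]
    rejected: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    def __iter__(self):
        return iter(self.tables)


def _parse_optional(value: str) -> Optional[str]:
    return None if value in ("", NA_TOKEN) else value


def _format_optional(value: Optional[str]) -> str:
    return NA_TOKEN if value is None else value


def tables_from_frame(df: pd.DataFrame) -> PsmParseResult:
    """Build :class:`SampleTable` objects from a frame in the PSM dialect.

    Rows with enrichment outside [0, 100] are rejected and reported; a
    non-numeric enrichment raises :class:`PsmRowError` with the offending
    line number (header = line 1).
    """
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise PsmFormatError(f"missing required column(s): {', '.join(missing)}")

    enr = pd.to_numeric(df["enrichment_pct"], errors="coerce")
    bad_numeric = enr.isna() & df["enrichment_pct"].astype(str).str.strip().ne("")
    bad_numeric |= df["enrichment_pct"].astype(str).str.strip().eq("")
    if bad_numeric.any():
        pos = int(np.flatnonzero(bad_numeric.to_numpy())[0])
        raise PsmRowError(
            pos + 2, f"non-numeric enrichment_pct {df['enrichment_pct'].iloc[pos]!r}"
        )

    rejected: list[tuple[int, str]] = []
    in_range = (enr >= 0.0) & (enr <= 100.0)
    for pos in np.flatnonzero(~in_range.to_numpy()):
        rejected.append(
            (int(pos) + 2, f"enrichment_pct {enr.iloc[int(pos)]} outside [0, 100]")
        )
    df = df.loc[in_range].assign(enrichment_pct=enr[in_range])

    tables: list[SampleTable] = []
    for sample_id, grp in df.groupby("sample_id", sort=False):
        psms = [
            PsmRecord(
                sample_id=str(sample_id),
                spectrum_id=str(row.spectrum_id),
                peptide=str(row.peptide),
                protein_ids=tuple(
                    dict.fromkeys(p for p in str(row.proteins).split(";") if p)
                ),
                enrichment_pct=float(row.enrichment_pct),
                taxon_order=_parse_optional(str(row.taxon_order)),
                taxon_genus=_parse_optional(str(row.taxon_genus)),
                cog_categories=frozenset(str(row.cog))
                if str(row.cog) not in ("", NA_TOKEN)
                else frozenset(),
            )
            for row in grp.itertuples(index=False)
        ]
        tables.append(SampleTable(sample_id=str(sample_id), psms=psms))
    if rejected:
        logger.warning("rejected %d PSM row(s) with out-of-range enrichment", len(rejected))
    return PsmParseResult(tables=tables, rejected=rejected)


def read_psm_table(path: str | Path) -> PsmParseResult:
    """Read a PSM TSV (UTF-8, tab-delimited, ``#`` comment lines allowed).

    Returns one :class:`SampleTable` per distinct ``sample_id`` in order of
    first appearance.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, comment="#", encoding="utf-8"
    )
    return tables_from_frame(df)


def psms_to_frame(tables: Iterable[SampleTable]) -> pd.DataFrame:
    rows = []
    for table in tables:
        for psm in table.psms:
            rows.append(
                {
                    "sample_id": psm.sample_id,
                    "spectrum_id": psm.spectrum_id,
                    "peptide": psm.peptide,
                    "proteins": ";".join(psm.protein_ids),
                    "enrichment_pct": psm.enrichment_pct,
                    "taxon_order": _format_optional(psm.taxon_order),
                    "taxon_genus": _format_optional(psm.taxon_genus),
                    "cog": "".join(sorted(psm.cog_categories)),
                }
            )
    return pd.DataFrame(rows, columns=PSM_COLUMNS)


def write_psm_table(tables: Iterable[SampleTable] | SampleTable, path: str | Path,
                    header_comment: Optional[str] = None) -> None:
    """Write sample tables back to the PSM TSV dialect."""
    if isinstance(tables, SampleTable):
        tables = [tables]
    df = psms_to_frame(tables)
    _write_tsv(df, path, header_comment)


def proteins_to_frame(tables: Iterable[SampleTable]) -> pd.DataFrame:
    rows = []
    for table in tables:
        for prot in table.proteins:
            rows.append(
                {
                    "sample_id": table.sample_id,
                    "protein_id": prot.protein_id,
                    "taxon_order": _format_optional(prot.taxon_order),
                    "taxon_genus": _format_optional(prot.taxon_genus),
                    "cog": "".join(sorted(prot.cog_categories)),
                    "n_unique_peptides": len(prot.peptides_unique),
                    "n_total_peptides": len(prot.peptides_unique)
                    + len(prot.peptides_shared),
                    "balanced_count": prot.balanced_count,
                    "relative_abundance": prot.relative_abundance,
                }
            )
    return pd.DataFrame(rows, columns=PROTEIN_COLUMNS)


def write_protein_table(tables: Iterable[SampleTable] | SampleTable, path: str | Path,
                        header_comment: Optional[str] = None) -> None:
    if isinstance(tables, SampleTable):
        tables = [tables]
    _write_tsv(proteins_to_frame(tables), path, header_comment)


def _write_tsv(df: pd.DataFrame, path: str | Path, header_comment: Optional[str]) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def _peptide_protein_maps(psms: Sequence[PsmRecord]):
    pep2prot: dict[str, set[str]] = {}
    for psm in psms:
        pep2prot.setdefault(psm.peptide, set()).update(psm.protein_ids)
    prot2peps: dict[str, set[str]] = {}
    for pep, prots in pep2prot.items():
        for prot in prots:
            prot2peps.setdefault(prot, set()).add(pep)
    return pep2prot, prot2peps


def _consensus(values: Iterable[Optional[str]]) -> tuple[Optional[str], bool]:
    """Single distinct non-missing value, else (None, conflict_flag)."""
    distinct = {v for v in values if v is not None}
    if len(distinct) == 1:
        return next(iter(distinct)), False
    return None, len(distinct) > 1


def apply_two_peptide_rule(table: SampleTable) -> SampleTable:
    """Filter proteins to those passing the two-peptide identification rule.

    A protein is identified only with at least one unique peptide plus at
    least one additional (unique or shared) peptide.  PSMs whose entire
    protein group fails the rule are flagged orphaned: they drop out of
    protein-level outputs but stay in the PSM list, because sample-level
    spectral metrics run over all PSMs.  Each surviving PSM's taxonomy is
    the consensus of its identified protein group; taxonomically mixed
    groups get missing taxonomy and the conflict is counted.
    """
    if not table.psms:
        logger.warning("sample %s: empty PSM table", table.sample_id)
        return SampleTable(table.sample_id, [], [], dict(table.metadata, two_peptide_applied=True))

    pep2prot, prot2peps = _peptide_protein_maps(table.psms)
    unique_peps = {
        prot: frozenset(p for p in peps if len(pep2prot[p]) == 1)
        for prot, peps in prot2peps.items()
    }
    identified = {
        prot
        for prot, peps in prot2peps.items()
        if len(unique_peps[prot]) >= 1 and len(peps) >= 2
    }

    # Protein annotations are the consensus over supporting PSMs.
    prot_psms: dict[str, list[PsmRecord]] = {p: [] for p in identified}
    for psm in table.psms:
        for prot in psm.protein_ids:
            if prot in identified:
                prot_psms[prot].append(psm)

    proteins = []
    for prot in sorted(identified):
        psms = prot_psms[prot]
        order, _ = _consensus(p.taxon_order for p in psms)
        genus, _ = _consensus(p.taxon_genus for p in psms)
        cogs = frozenset().union(*(p.cog_categories for p in psms))
        proteins.append(
            ProteinRecord(
                protein_id=prot,
                peptides_unique=unique_peps[prot],
                peptides_shared=frozenset(prot2peps[prot]) - unique_peps[prot],
                taxon_order=order,
                taxon_genus=genus if order is not None else None,
                cog_categories=cogs,
            )
        )
    by_id = {p.protein_id: p for p in proteins}

    new_psms = []
    n_orphaned = 0
    n_conflicts = 0
    for psm in table.psms:
        group = [by_id[p] for p in psm.protein_ids if p in identified]
        if not group:
            n_orphaned += 1
            new_psms.append(replace(psm, orphaned=True))
            continue
        order, conflict_o = _consensus(g.taxon_order for g in group)
        genus, conflict_g = _consensus(g.taxon_genus for g in group)
        if conflict_o or conflict_g:
            n_conflicts += 1
        new_psms.append(
            replace(
                psm,
                orphaned=False,
                taxon_order=order,
                taxon_genus=genus if order is not None else None,
            )
        )

    metadata = dict(table.metadata)
    metadata.update(
        two_peptide_applied=True,
        n_orphaned=n_orphaned,
        taxon_conflicts=n_conflicts,
        natural_abundance_pct=NATURAL_ABUNDANCE_PCT,
    )
    return SampleTable(table.sample_id, new_psms, proteins, metadata)


def balanced_spectral_counts(table: SampleTable) -> SampleTable:
    """Distribute each PSM's unit count over its identified proteins.

    Unique-peptide PSMs give their whole count to the one protein; shared
    PSMs split proportionally to each candidate protein's unique-peptide PSM
    count (equally when every candidate has zero).  Orphaned PSM counts
    accumulate in the sample's unassigned bucket.  Relative abundance is the
    protein's balanced count over the sample's assigned total.
    """
    if not table.metadata.get("two_peptide_applied"):
        raise ValueError("apply_two_peptide_rule must run before balanced counting")

    pep2prot, _ = _peptide_protein_maps(table.psms)
    by_id = {p.protein_id: p for p in table.proteins}

    unique_psm_count: dict[str, int] = {p: 0 for p in by_id}
    for psm in table.psms:
        if len(pep2prot[psm.peptide]) == 1:
            prot = next(iter(pep2prot[psm.peptide]))
            if prot in unique_psm_count:
                unique_psm_count[prot] += 1

    counts: dict[str, float] = {p: 0.0 for p in by_id}
    unassigned = 0.0
    for psm in table.psms:
        candidates = [p for p in psm.protein_ids if p in by_id]
        if not candidates:
            unassigned += 1.0
            continue
        if len(candidates) == 1:
            counts[candidates[0]] += 1.0
            continue
        ucounts = np.array([unique_psm_count[p] for p in candidates], dtype=float)
        if ucounts.sum() == 0:
            shares = np.full(len(candidates), 1.0 / len(candidates))
        else:
            shares = ucounts / ucounts.sum()
        for prot, share in zip(candidates, shares):
            counts[prot] += share

    total = sum(counts.values())
    proteins = [
        replace(
            prot,
            balanced_count=counts[prot.protein_id],
            relative_abundance=(counts[prot.protein_id] / total) if total > 0 else 0.0,
        )
        for prot in table.proteins
    ]
    if unassigned:
        logger.info(
            "sample %s: %.0f PSM(s) in unassigned bucket", table.sample_id, unassigned
        )
    return SampleTable(
        table.sample_id,
        list(table.psms),
        proteins,
        dict(table.metadata, balanced_counts_applied=True),
        unassigned_weight=unassigned,
    )


def process_sample(table: SampleTable) -> SampleTable:
    """Two-peptide rule followed by balanced spectral counting."""
    return balanced_spectral_counts(apply_two_peptide_rule(table))
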