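"""Synthetic PSM tables with recorded ground truth.

The generator emulates the output of an isotope-aware database search over
a mixed bacterioplankton community: each PSM gets a taxon (multinomial
community composition), a protein and peptide within that taxon (with a
configurable shared-peptide fraction), a COG letter inherited from its
protein, and a percent 13C enrichment.  Unlabeled PSMs sit near the 1.109%
natural abundance, strictly below the 2% labeling threshold; labeled PSMs
draw from a per-taxon mixture of normals truncated to [threshold, 100] and
snapped to the 1% search grid.  The default experiment reproduces the
study design the analysis expects: triplicate 15-h and 32-h samples from
one location (MB1a–c, MB2a–c) plus single samples at both time points from
a second (OR1, OR2), with the 32-h and OR communities shifted from a
unimodal labeled-enrichment mode near 35% to a bimodal mixture (modes near
17% and 60%) and proportionally higher labeling.

Every generated dataset carries its ground truth (true per-taxon labeling
probability and mixture) so recovery tests can compare estimates against
the configured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .permutation import derive_seed
from .psm_io import LABEL_THRESHOLD_PCT, NATURAL_ABUNDANCE_PCT, PSM_COLUMNS

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: Labeled-enrichment mixture of the early (15 h) community: a large
#: barely-labeled component just above threshold plus the ~35% mode, which
#: together give average enrichments near 15%.
UNIMODAL_EARLY_MIXTURE = ((0.62, 3.0, 1.5), (0.38, 35.0, 8.0))

#: Later / second-location mixture: bimodal with modes near 17% and 60%
#: plus the barely-labeled component; average enrichment near 28%.
BIMODAL_LATE_MIXTURE = ((0.33, 3.0, 1.5), (0.28, 17.0, 3.0), (0.39, 60.0, 10.0))

DEFAULT_COG_DISTRIBUTION = {
    "J": 0.16, "E": 0.12, "C": 0.10, "G": 0.09, "O": 0.08,
    "P": 0.06, "T": 0.05, "F": 0.04, "I": 0.04, "M": 0.06,
}


class SyntheticConfigError(ValueError):
    """The synthetic configuration is inconsistent."""


@dataclass(frozen=True)
class TaxonProfile:
    """Ground-truth generative profile of one taxon."""

    taxon_order: Optional[str]
    taxon_genus: Optional[str]
    proportion: float
    p_label: float
    enrichment_mixture: tuple[tuple[float, float, float], ...]  # (weight, mode, sd)
    cog_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COG_DISTRIBUTION)
    )
    n_proteins: int = 40
    shared_peptide_fraction: float = 0.2

    def validate(self) -> None:
        if not 0 <= self.p_label <= 1:
            raise SyntheticConfigError("p_label must be in [0, 1]")
        if not 0 <= self.proportion <= 1:
            raise SyntheticConfigError("proportion must be in [0, 1]")
        weights = sum(w for w, _, _ in self.enrichment_mixture)
        if abs(weights - 1.0) > 1e-9:
            raise SyntheticConfigError(
                f"mixture weights sum to {weights}, expected 1"
            )
        if sum(self.cog_distribution.values()) > 1 + 1e-9:
            raise SyntheticConfigError("COG probabilities must sum to <= 1")
        if not 0 <= self.shared_peptide_fraction < 1:
            raise SyntheticConfigError("shared_peptide_fraction must be in [0, 1)")
        if self.n_proteins < 1:
            raise SyntheticConfigError("n_proteins must be >= 1")

    def mixture_spec(self) -> str:
        return ";".join(
            f"{w:g}@{m:g}sd{s:g}" for w, m, s in self.enrichment_mixture
        )


@dataclass(frozen=True)
class SamplePlan:
    """One sample of the experiment design."""

    sample_id: str
    location: str
    incubation_h: float
    p_label_factor: float = 1.0
    mixture: Optional[tuple[tuple[float, float, float], ...]] = None


@dataclass(frozen=True)
class SyntheticConfig:
    taxa: tuple[TaxonProfile, ...]
    plans: tuple[SamplePlan, ...]
    n_psm: int = 20000
    threshold: float = LABEL_THRESHOLD_PCT
    seed: int = 0

    def validate(self) -> None:
        if self.n_psm <= 0:
            raise SyntheticConfigError("n_psm must be positive")
        total = sum(t.proportion for t in self.taxa)
        if abs(total - 1.0) > 1e-9:
            raise SyntheticConfigError(
                f"taxa proportions sum to {total}, expected 1"
            )
        for taxon in self.taxa:
            taxon.validate()
        ids = [p.sample_id for p in self.plans]
        if len(set(ids)) != len(ids):
            raise SyntheticConfigError("sample ids must be unique")


def default_taxa() -> tuple[TaxonProfile, ...]:
    """A nine-group coastal community with differential DFAA labeling.

    Proportions and labeling probabilities give a pooled label frequency
    near 2.5% at 15 h, roughly doubling by 32 h and ~4x higher at the
    second location once the plan factors apply.
    """
    rows = [
        ("Rhodobacterales", "Planktomarina", 0.20, 0.045),
        ("Rhodobacterales", "Roseobacter", 0.08, 0.040),
        ("Alteromonadales", "Alteromonas", 0.13, 0.035),
        ("Alteromonadales", "Glaciecola", 0.05, 0.030),
        ("Flavobacteriales", "Polaribacter", 0.14, 0.012),
        ("Pelagibacterales", "Pelagibacter", 0.14, 0.006),
        ("Oceanospirillales", "Neptuniibacter", 0.08, 0.020),
        ("Cellvibrionales", "Porticoccus", 0.06, 0.020),
        (None, None, 0.12, 0.010),
    ]
    return tuple(
        TaxonProfile(
            taxon_order=order,
            taxon_genus=genus,
            proportion=prop,
            p_label=p_label,
            enrichment_mixture=UNIMODAL_EARLY_MIXTURE,
        )
        for order, genus, prop, p_label in rows
    )


def default_plans() -> tuple[SamplePlan, ...]:
    """Triplicates at two time points plus two single samples."""
    late = BIMODAL_LATE_MIXTURE
    plans = [
        SamplePlan(f"MB1{r}", "MB", 15) for r in "abc"
    ] + [
        SamplePlan(f"MB2{r}", "MB", 32, p_label_factor=1.95, mixture=late)
        for r in "abc"
    ] + [
        SamplePlan("OR1", "OR", 15, p_label_factor=3.8, mixture=late),
        SamplePlan("OR2", "OR", 32, p_label_factor=4.26, mixture=late),
    ]
    return tuple(plans)


def default_config(seed: int = 0, n_psm: int = 20000) -> SyntheticConfig:
    return SyntheticConfig(
        taxa=default_taxa(), plans=default_plans(), n_psm=n_psm, seed=seed
    )


def sample_enrichment(
    profile: TaxonProfile,
    labeled: bool,
    rng: np.random.Generator,
    threshold: float = LABEL_THRESHOLD_PCT,
) -> float:
    """Draw one enrichment percent for a PSM of this taxon."""
    if labeled:
        return float(
            _labeled_enrichments(profile.enrichment_mixture, 1, rng, threshold)[0]
        )
    return float(_unlabeled_enrichments(1, rng, threshold)[0])


def _unlabeled_enrichments(
    n: int, rng: np.random.Generator, threshold: float
) -> np.ndarray:
    # natural abundance plus +-0.5% jitter, truncated below the threshold
    values = NATURAL_ABUNDANCE_PCT + rng.uniform(-0.5, 0.5, size=n)
    return np.minimum(values, np.nextafter(threshold, -np.inf))


def _labeled_enrichments(
    mixture: Sequence[tuple[float, float, float]],
    n: int,
    rng: np.random.Generator,
    threshold: float,
) -> np.ndarray:
    weights = np.array([w for w, _, _ in mixture])
    if abs(weights.sum() - 1.0) > 1e-9:
        raise SyntheticConfigError("mixture weights must sum to 1")
    modes = np.array([m for _, m, _ in mixture])
    sds = np.array([s for _, _, s in mixture])
    comp = rng.choice(len(mixture), size=n, p=weights)
    values = rng.normal(modes[comp], sds[comp])
    values = np.clip(values, threshold, 100.0)
    # snap to the 1% search grid, then re-clip (rounding can cross bounds)
    return np.clip(np.rint(values), threshold, 100.0)


def _protein_ids(config: SyntheticConfig) -> list[list[str]]:
    ids = []
    for t, profile in enumerate(config.taxa):
        slug = (profile.taxon_genus or "unk").lower()
        ids.append([f"t{t:02d}_{slug}_p{j:03d}" for j in range(profile.n_proteins)])
    return ids


def _peptide_pools(config: SyntheticConfig):
    """Per-protein unique peptides and within-taxon shared peptides.

    Seeded from the config seed only, so peptide identities are stable
    across the samples of one experiment.
    """
    rng = np.random.default_rng(derive_seed(config.seed, "peptides"))
    seen: set[str] = set()

    def fresh_peptide() -> str:
        while True:
            pep = "".join(rng.choice(_AMINO_ACIDS, size=10))
            if pep not in seen:
                seen.add(pep)
                return pep

    unique, shared = [], []
    for profile in config.taxa:
        unique.append(
            [[fresh_peptide() for _ in range(3)] for _ in range(profile.n_proteins)]
        )
        shared.append([fresh_peptide() for _ in range(profile.n_proteins)])
    return unique, shared


def _protein_cogs(config: SyntheticConfig) -> list[list[str]]:
    """One COG letter (or none) per protein, stable across samples."""
    rng = np.random.default_rng(derive_seed(config.seed, "cogs"))
    cogs = []
    for profile in config.taxa:
        letters = list(profile.cog_distribution)
        probs = np.array([profile.cog_distribution[c] for c in letters])
        p_none = max(0.0, 1.0 - probs.sum())
        choices = letters + [""]
        p = np.append(probs, p_none)
        p = p / p.sum()
        cogs.append(
            [str(rng.choice(choices, p=p)) for _ in range(profile.n_proteins)]
        )
    return cogs


def _plan_profiles(config: SyntheticConfig, plan: SamplePlan) -> list[TaxonProfile]:
    out = []
    for profile in config.taxa:
        out.append(
            replace(
                profile,
                p_label=min(1.0, profile.p_label * plan.p_label_factor),
                enrichment_mixture=plan.mixture or profile.enrichment_mixture,
            )
        )
    return out


def generate_sample(
    config: SyntheticConfig, plan: SamplePlan
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One sample's PSM table (dialect frame) and its ground truth."""
    config.validate()
    profiles = _plan_profiles(config, plan)
    rng = np.random.default_rng(derive_seed(config.seed, "sample", plan.sample_id))
    n = config.n_psm

    proportions = np.array([p.proportion for p in profiles])
    p_label = np.array([p.p_label for p in profiles])
    shared_frac = np.array([p.shared_peptide_fraction for p in profiles])
    n_proteins = np.array([p.n_proteins for p in profiles])

    taxon_idx = rng.choice(len(profiles), size=n, p=proportions)
    protein_idx = rng.integers(0, n_proteins[taxon_idx])
    shared = rng.random(n) < shared_frac[taxon_idx]
    shared &= n_proteins[taxon_idx] >= 2
    labeled = rng.random(n) < p_label[taxon_idx]
    slot = rng.integers(0, 3, size=n)

    enrichment = _unlabeled_enrichments(n, rng, config.threshold)
    for t, profile in enumerate(profiles):
        mask = labeled & (taxon_idx == t)
        m = int(mask.sum())
        if m:
            enrichment[mask] = _labeled_enrichments(
                profile.enrichment_mixture, m, rng, config.threshold
            )

    prot_ids = _protein_ids(config)
    unique_peps, shared_peps = _peptide_pools(config)
    prot_cogs = _protein_cogs(config)

    peptides, proteins_col, cog_col, order_col, genus_col = [], [], [], [], []
    for i in range(n):
        t = int(taxon_idx[i])
        j = int(protein_idx[i])
        profile = profiles[t]
        if shared[i]:
            j2 = (j + 1) % profile.n_proteins
            peptides.append(shared_peps[t][j])
            proteins_col.append(f"{prot_ids[t][j]};{prot_ids[t][j2]}")
            cog_col.append("".join(sorted(set(prot_cogs[t][j] + prot_cogs[t][j2]))))
        else:
            peptides.append(unique_peps[t][j][int(slot[i])])
            proteins_col.append(prot_ids[t][j])
            cog_col.append(prot_cogs[t][j])
        order_col.append(profile.taxon_order or "NA")
        genus_col.append(profile.taxon_genus or "NA")

    frame = pd.DataFrame(
        {
            "sample_id": plan.sample_id,
            "spectrum_id": [f"{plan.sample_id}.{i + 1:05d}" for i in range(n)],
            "peptide": peptides,
            "proteins": proteins_col,
            "enrichment_pct": np.round(enrichment, 3),
            "taxon_order": order_col,
            "taxon_genus": genus_col,
            "cog": cog_col,
        },
        columns=PSM_COLUMNS,
    )

    truth_rows = []
    for t, profile in enumerate(profiles):
        mask = taxon_idx == t
        truth_rows.append(
            {
                "sample_id": plan.sample_id,
                "taxon_order": profile.taxon_order or "NA",
                "taxon_genus": profile.taxon_genus or "NA",
                "proportion": profile.proportion,
                "p_label": profile.p_label,
                "mixture_spec": profile.mixture_spec(),
                "n_psm_realized": int(mask.sum()),
                "n_labeled_realized": int((mask & labeled).sum()),
            }
        )
    return frame, pd.DataFrame(truth_rows)


def generate_experiment(
    config: SyntheticConfig,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """All samples of the design; returns frames keyed by sample id plus truth."""
    config.validate()
    frames: dict[str, pd.DataFrame] = {}
    truths = []
    for plan in config.plans:
        frame, truth = generate_sample(config, plan)
        frames[plan.sample_id] = frame
        truths.append(truth)
    return frames, pd.concat(truths, ignore_index=True)


def write_experiment(config: SyntheticConfig, outdir: str | Path) -> list[Path]:
    """Generate and write one TSV per sample plus the ground-truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames, truth = generate_experiment(config)
    written = []
    for sample_id, frame in frames.items():
        path = outdir / f"{sample_id}.psms.tsv"
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(f"# protsip synthetic sample seed={config.seed}\n")
            frame.to_csv(fh, sep="\t", index=False, float_format="%.10g",
                         lineterminator="\n")
        written.append(path)
    truth_path = outdir / "ground_truth.tsv"
    with open(truth_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# protsip ground truth seed={config.seed}\n")
        truth.to_csv(fh, sep="\t", index=False, float_format="%.10g",
                     lineterminator="\n")
    written.append(truth_path)
    return written


def _mixture_from_obj(obj) -> tuple[tuple[float, float, float], ...]:
    return tuple((float(w), float(m), float(s)) for w, m, s in obj)


def config_from_yaml(path: str | Path) -> SyntheticConfig:
    """Load a generator configuration from a YAML file.

    Top-level keys: ``seed``, ``n_psm``, ``threshold``, ``taxa`` (list of
    profiles) and optional ``samples`` (list of plans; the default 8-sample
    design when omitted).
    """
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    try:
        taxa = tuple(
            TaxonProfile(
                taxon_order=t.get("taxon_order"),
                taxon_genus=t.get("taxon_genus"),
                proportion=float(t["proportion"]),
                p_label=float(t["p_label"]),
                enrichment_mixture=_mixture_from_obj(t["enrichment_mixture"]),
                cog_distribution={
                    str(k): float(v)
                    for k, v in t.get(
                        "cog_distribution", DEFAULT_COG_DISTRIBUTION
                    ).items()
                },
                n_proteins=int(t.get("n_proteins", 40)),
                shared_peptide_fraction=float(t.get("shared_peptide_fraction", 0.2)),
            )
            for t in doc["taxa"]
        )
        if "samples" in doc:
            plans = tuple(
                SamplePlan(
                    sample_id=str(s["sample_id"]),
                    location=str(s.get("location", "NA")),
                    incubation_h=float(s.get("incubation_h", 0)),
                    p_label_factor=float(s.get("p_label_factor", 1.0)),
                    mixture=_mixture_from_obj(s["mixture"]) if s.get("mixture") else None,
                )
                for s in doc["samples"]
            )
        else:
            plans = default_plans()
        config = SyntheticConfig(
            taxa=taxa,
            plans=plans,
            n_psm=int(doc.get("n_psm", 20000)),
            threshold=float(doc.get("threshold", LABEL_THRESHOLD_PCT)),
            seed=int(doc.get("seed", 0)),
        )
    except (KeyError, TypeError) as exc:
        raise SyntheticConfigError(f"malformed synthetic config: {exc}") from exc
    config.validate()
    return config
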