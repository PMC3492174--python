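"""Per-site nuisance features and likelihood preferences.

For a focal phylogenetic question, every alignment column gets:

* its ML rate multiplier averaged over the competing hypotheses,
* GC content and missing-data proportion within each clade of interest,
* per-hypothesis log-likelihood scores (LLS) and the *preferred topology*
  (the hypothesis with the highest LLS at that site).

The assembled table is the input to the discriminant analysis: if the
nuisance features alone predict a site's preferred topology well, that
preference is suspected to reflect bias rather than history.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .phylolik import (
    FitResult,
    HypothesisSet,
    SiteLikelihoodMatrix,
    estimate_site_rates,
    site_lls_for_hypotheses,
)
from .seqio import Alignment

__all__ = [
    "CladeDefinition",
    "SiteTable",
    "clade_gc_profile",
    "clade_missing_profile",
    "preferred_topology",
    "preferred_topologies",
    "build_site_table",
    "read_question_config",
    "UNINFORMATIVE",
]

UNINFORMATIVE = "uninformative"


@dataclass
class CladeDefinition:
    """A named group of taxa over which composition/missingness is averaged."""

    name: str
    taxa: list[str]

    def __post_init__(self) -> None:
        if not self.taxa:
            raise ValueError(f"clade {self.name!r} is empty")

    def validate_against(self, aln: Alignment) -> None:
        unknown = set(self.taxa) - set(aln.taxa)
        if unknown:
            raise ValueError(
                f"clade {self.name!r} has unknown taxa: {sorted(unknown)}"
            )


def _clade_rows(aln: Alignment, clade: CladeDefinition) -> np.ndarray:
    clade.validate_against(aln)
    return aln.matrix[[aln.taxa.index(t) for t in clade.taxa]]


def clade_gc_profile(aln: Alignment, clade: CladeDefinition,
                     impute: bool = True) -> np.ndarray:
    """Per-site GC fraction among clade taxa: (#G+#C)/(#A+#C+#G+#T).

    Ambiguity codes and missing characters are excluded from numerator and
    denominator.  Sites where no clade taxon has an unambiguous base are NA
    and, with `impute`, filled with the feature's mean over other sites.
    """
    if aln.alphabet != "nt":
        raise ValueError("GC profile requires a nucleotide alignment")
    rows = _clade_rows(aln, clade)
    gc = np.isin(rows, ["G", "C"]).sum(axis=0).astype(float)
    acgt = np.isin(rows, ["A", "C", "G", "T"]).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = gc / acgt
    if impute and np.isnan(frac).any():
        mean = np.nanmean(frac) if np.isfinite(np.nanmean(frac)) else 0.5
        frac = np.where(np.isnan(frac), mean, frac)
    return frac


def clade_missing_profile(aln: Alignment, clade: CladeDefinition) -> np.ndarray:
    """Per-site fraction of clade taxa with missing data ('-', '?', N/X)."""
    rows = _clade_rows(aln, clade)
    miss = np.isin(rows, list(aln.missing_chars)).sum(axis=0)
    return miss / len(clade.taxa)


def preferred_topology(lls_row, names: list[str],
                       tolerance: float = 1e-9) -> str:
    """The hypothesis with the highest LLS, or 'uninformative' on a tie."""
    row = np.asarray(lls_row, float)
    order = np.argsort(row)[::-1]
    if len(row) > 1 and row[order[0]] - row[order[1]] < tolerance:
        return UNINFORMATIVE
    return names[order[0]]


def preferred_topologies(lls: np.ndarray, names: list[str],
                         tolerance: float = 1e-9) -> np.ndarray:
    lls = np.asarray(lls, float)
    part = np.sort(lls, axis=1)
    best = lls.argmax(axis=1)
    out = np.array([names[b] for b in best], dtype=object)
    if lls.shape[1] > 1:
        ties = (part[:, -1] - part[:, -2]) < tolerance
        out[ties] = UNINFORMATIVE
    return out


@dataclass
class SiteTable:
    """Per-site features, LLS columns and preferred-topology labels."""

    df: pd.DataFrame
    clade_names: list[str] = field(default_factory=list)
    hypothesis_names: list[str] = field(default_factory=list)

    FEATURE_SETS = {
        "rate": ("rate",),
        "rate+missing": ("rate", "miss_"),
        "rate+gc": ("rate", "gc_"),
        "rate+gc+missing": ("rate", "gc_", "miss_"),
    }

    @property
    def n_sites(self) -> int:
        return len(self.df)

    @property
    def informative_mask(self) -> np.ndarray:
        return (self.df["preferred"] != UNINFORMATIVE).to_numpy()

    def feature_columns(self, feature_set: str = "rate+gc+missing") -> list[str]:
        keys = self.FEATURE_SETS[feature_set]
        cols = []
        for c in self.df.columns:
            if c in keys or any(c.startswith(k) for k in keys if k.endswith("_")):
                cols.append(c)
        return cols

    def features(self, feature_set: str = "rate+gc+missing") -> pd.DataFrame:
        return self.df[self.feature_columns(feature_set)]

    def lls_matrix(self) -> SiteLikelihoodMatrix:
        cols = [f"lls_{h}" for h in self.hypothesis_names]
        sub = self.df[cols].copy()
        sub.columns = self.hypothesis_names
        sub.index = self.df["site"].to_numpy()
        return SiteLikelihoodMatrix(sub)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.8g")

    @classmethod
    def from_tsv(cls, path) -> "SiteTable":
        df = pd.read_csv(path, sep="\t")
        clades = sorted({c[3:] for c in df.columns if c.startswith("gc_")})
        hyps = [c[4:] for c in df.columns if c.startswith("lls_")]
        return cls(df, clades, hyps)


def build_site_table(
    aln: Alignment,
    hypotheses: HypothesisSet,
    clades: list[CladeDefinition],
    model=None,
    tolerance: float = 1e-9,
    lls: SiteLikelihoodMatrix | None = None,
    fits: dict[str, FitResult] | None = None,
    site_rates: np.ndarray | None = None,
    **fit_kwargs,
) -> SiteTable:
    """Assemble the per-site feature/preference table for one question.

    Fits every hypothesis (unless pre-computed results are passed), derives
    site rates, clade GC and missingness profiles, per-hypothesis LLS and
    the preferred topology per site.  Deterministic given its inputs.
    """
    for c in clades:
        c.validate_against(aln)
    if lls is None or fits is None:
        lls, fits = site_lls_for_hypotheses(aln, hypotheses, model, **fit_kwargs)
    if site_rates is None:
        site_rates = estimate_site_rates(aln, fits)
    data: dict[str, np.ndarray] = {
        "site": np.arange(1, aln.n_sites + 1),
        "rate": np.asarray(site_rates, float),
    }
    if aln.alphabet == "nt":
        for c in clades:
            data[f"gc_{c.name}"] = clade_gc_profile(aln, c)
    for c in clades:
        data[f"miss_{c.name}"] = clade_missing_profile(aln, c)
    names = lls.hypothesis_names
    for h in names:
        data[f"lls_{h}"] = lls.df[h].to_numpy()
    preferred = preferred_topologies(lls.values, names, tolerance)
    data["preferred"] = preferred
    data["informative"] = preferred != UNINFORMATIVE
    return SiteTable(pd.DataFrame(data), [c.name for c in clades], list(names))


def read_question_config(path):
    """Read a clade/hypothesis configuration file (YAML).

    Expected structure::

        clades:
          turtles: [taxon1, taxon2]
          ...
        hypotheses:
          turtle_archosaur: trees/turtle_archosaur.nwk
          ...
    """
    from .seqio import read_trees

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    clades = [CladeDefinition(k, list(v)) for k, v in raw.get("clades", {}).items()]
    hyps = {}
    for name, tree_path in raw.get("hypotheses", {}).items():
        trees = read_trees(tree_path)
        if len(trees) != 1:
            raise ValueError(f"expected one tree in {tree_path}")
        hyps[name] = trees[0]
    return clades, HypothesisSet(hyps) if hyps else None
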