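"""Trait preparation: diet diversity, transforms, per-group analysis datasets.

Diet generalism is summarised by the Shannon index over diet-category
proportions.  Continuous predictors are (optionally log-) transformed and
z-scored within each analysis dataset, since path coefficients are
reported on the standardized scale per group.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tree import Phylogeny, prune

log = logging.getLogger(__name__)

__all__ = [
    "shannon_diversity",
    "add_diet_diversity",
    "transform_and_standardize",
    "StandardizedDesign",
    "assemble_order_dataset",
    "DatasetSkipped",
]


def shannon_diversity(
    proportions,
    base: float | None = None,
    renormalize: bool = False,
    tol: float = 1e-6,
) -> float:
    """Shannon diversity H = −Σ p_i log p_i of a composition.

    Zero proportions contribute nothing.  ``base`` switches the logarithm
    base (natural log by default, so H is in nats and the 10-category
    maximum is ln 10).  Proportions must sum to 1 within ``tol`` unless
    ``renormalize`` is set, in which case they are rescaled with a warning.
    """
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0) or np.any(p > 1 + tol):
        raise ValueError("proportions must lie in [0, 1]")
    total = p.sum()
    if abs(total - 1.0) > tol:
        if not renormalize:
            raise ValueError(
                f"proportions sum to {total:.6g}, not 1; pass renormalize=True "
                "to rescale"
            )
        warnings.warn("renormalizing diet proportions to sum to 1", stacklevel=2)
        p = p / total
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def add_diet_diversity(
    table: pd.DataFrame,
    diet_cols: list[str],
    out_col: str = "diet_diversity",
    base: float | None = None,
    renormalize: bool = False,
) -> pd.DataFrame:
    """Append a Shannon diet-diversity column computed from proportion columns."""
    out = table.copy()
    out[out_col] = [
        shannon_diversity(row, base=base, renormalize=renormalize)
        for row in table[diet_cols].to_numpy()
    ]
    return out


@dataclass
class StandardizedDesign:
    """Analysis-ready design: z-scored continuous traits plus a binary outcome.

    ``data`` holds one column per continuous variable (mean 0, sd 1) and
    the untransformed 0/1 column named ``binary_var``.
    """

    data: pd.DataFrame
    species: list[str]
    continuous_vars: list[str]
    binary_var: str
    transform_params: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.data)

    def __post_init__(self) -> None:
        for v in self.continuous_vars:
            col = self.data[v].to_numpy(dtype=float)
            if abs(col.mean()) > 1e-8 or abs(col.std(ddof=1) - 1.0) > 1e-8:
                raise ValueError(f"column {v!r} is not standardized")
        b = set(self.data[self.binary_var].unique())
        if not b <= {0, 1}:
            raise ValueError(f"binary column {self.binary_var!r} is not 0/1")

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)


def transform_and_standardize(
    table: pd.DataFrame,
    continuous_vars: list[str],
    binary_var: str,
    species_col: str = "species",
    log_vars: set[str] | None = None,
) -> StandardizedDesign:
    """Log-transform ``log_vars`` (natural log), then z-score all continuous
    variables within the dataset.  The binary column is left untouched.

    Back-transformation parameters (mean, sd per column) are retained in
    ``transform_params`` so original values can be recovered exactly.
    """
    log_vars = set(log_vars or ())
    unknown = log_vars - set(continuous_vars)
    if unknown:
        raise KeyError(f"log_vars not among continuous_vars: {sorted(unknown)}")
    data = {}
    params = {}
    for v in continuous_vars:
        x = table[v].to_numpy(dtype=float)
        logged = v in log_vars
        if logged:
            if np.any(x <= 0):
                bad = table.loc[table[v] <= 0, species_col].tolist()
                raise ValueError(
                    f"nonpositive values in log-transformed {v!r} for: {bad}"
                )
            x = np.log(x)
        mu, sd = float(x.mean()), float(x.std(ddof=1))
        if sd == 0:
            raise ValueError(f"column {v!r} is constant; cannot standardize")
        data[v] = (x - mu) / sd
        params[v] = {"log": logged, "mean": mu, "sd": sd}
    data[binary_var] = table[binary_var].to_numpy(dtype=int)
    species = [str(s) for s in table[species_col]]
    return StandardizedDesign(
        data=pd.DataFrame(data, index=species),
        species=species,
        continuous_vars=list(continuous_vars),
        binary_var=binary_var,
        transform_params=params,
    )


class DatasetSkipped(Exception):
    """Raised when a per-group dataset fails the minimum-size rule."""


def _realm_set(value) -> set[str]:
    return {r.strip().lower() for r in str(value).split(";") if r.strip()}


def assemble_order_dataset(
    table: pd.DataFrame,
    tree: Phylogeny,
    order: str,
    urban_class: str,
    schema: dict,
    continuous_vars: list[str],
    log_vars: set[str] | None = None,
    realm_filter: bool = True,
    min_n: int = 20,
) -> tuple[StandardizedDesign, Phylogeny]:
    """Build the analysis dataset for one taxonomic order and urban class.

    Species of the order with complete traits are retained; non-urban
    species are restricted to the biogeographic realms where urban species
    of the order occur; species unambiguously belonging to the complementary
    urban class are excluded; the tree is pruned to the result.  A dataset
    with fewer than ``min_n`` species raises :class:`DatasetSkipped`.
    """
    if urban_class not in ("visitor", "dweller"):
        raise ValueError("urban_class must be 'visitor' or 'dweller'")
    sp_col, urban_col = schema["species"], schema["urban"]
    order_col, realm_col = schema.get("order"), schema.get("realm")
    sub = table
    if order_col:
        sub = sub[sub[order_col] == order]
    if sub.empty:
        raise KeyError(f"order {order!r} not present in table")
    other = "dweller" if urban_class == "visitor" else "visitor"
    u = sub[urban_col]
    if u.dtype == object:
        positive = u.isin([urban_class, "both"])
        excluded = u == other
    else:  # already binary: nothing to exclude
        positive = u == 1
        excluded = pd.Series(False, index=sub.index)
    sub = sub[~excluded]
    positive = positive[~excluded]
    if realm_filter and realm_col:
        urban_realms: set[str] = set()
        for v in sub.loc[positive, realm_col]:
            urban_realms |= _realm_set(v)
        in_realm = sub[realm_col].map(lambda v: bool(_realm_set(v) & urban_realms))
        sub = sub[positive | in_realm]
        positive = positive[sub.index]
    on_tree = sub[sp_col].isin(set(tree.taxa))
    n_off = int((~on_tree).sum())
    if n_off:
        log.warning(
            "%d species of order %s not on the tree: %s",
            n_off, order, sorted(sub.loc[~on_tree, sp_col])[:10],
        )
    sub = sub[on_tree]
    positive = positive[sub.index]
    if len(sub) < 2:
        raise ValueError(f"fewer than 2 species remain for {order}/{urban_class}")
    if len(sub) < min_n:
        raise DatasetSkipped(
            f"{order}/{urban_class}: n={len(sub)} < min_n={min_n}"
        )
    sub = sub.copy()
    binary_var = "urban"
    sub[binary_var] = positive.astype(int).to_numpy()
    design = transform_and_standardize(
        sub, continuous_vars, binary_var, species_col=sp_col, log_vars=log_vars
    )
    return design, prune(tree, design.species)
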