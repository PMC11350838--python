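"""Binned exposure odds ratios against a switchable reference bin.

Exposure is cut into left-closed, right-open bins (the last bin is closed
on the right); crude ORs come from 2x2 cross-products against the
reference bin, adjusted ORs from a single logistic fit with bin indicators
plus the full adjustment set and site intercepts.  Re-referencing is a
contrast operation on the fitted coefficients -- no refit.

Sparse bins (fewer than 5 subjects in either arm) are merged into their
lower neighbour with a warning before fitting, mirroring how published
tables bracket their sparse top-exposure categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .logistic import DesignSpec, LogisticFit, encode_covariates, fit_logistic, wald_or_ci

__all__ = ["DEFAULT_EDGES", "BinScheme", "BinnedORTable", "assign_bins", "binned_or_table"]

#: Default bin edges in Bq/m^3 (25/50/100-wide bins, top edge at the
#: exposure support maximum).
DEFAULT_EDGES = (4.0, 25.0, 50.0, 75.0, 100.0, 150.0, 200.0, 250.0, 300.0, 400.0, 835.0)

MIN_PER_ARM = 5


@dataclass(frozen=True)
class BinScheme:
    """Strictly increasing edges defining ``len(edges) - 1`` exposure bins."""

    edges: tuple[float, ...] = DEFAULT_EDGES
    reference_bin: int = 0

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, float)
        if len(e) < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("edges must be strictly increasing with at least two values")
        if not 0 <= self.reference_bin < len(e) - 1:
            raise ValueError("reference_bin out of range")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def label(self, i: int) -> str:
        lo, hi = self.edges[i], self.edges[i + 1]
        fmt = lambda v: f"{v:g}"
        if i == self.n_bins - 1:
            return f"{fmt(lo)}-{fmt(hi)}"
        return f"{fmt(lo)}-<{fmt(hi)}"


def assign_bins(values, scheme: BinScheme) -> np.ndarray:
    """Half-open [lo, hi) bin index per value; the last bin is closed.

    Values below the first edge or above the last raise ``ValueError``.
    """
    v = np.asarray(values, float)
    edges = np.asarray(scheme.edges, float)
    if np.any(v < edges[0]):
        raise ValueError(f"exposure value below the first bin edge {edges[0]}")
    if np.any(v > edges[-1]):
        raise ValueError(f"exposure value above the last bin edge {edges[-1]}")
    idx = np.digitize(v, edges) - 1
    return np.minimum(idx, scheme.n_bins - 1)


@dataclass
class BinnedORTable:
    """Per-bin counts with crude and adjusted ORs against a reference bin.

    ``table`` columns: bin label, edges, counts, mean sIR, crude OR with
    Woolf CI, adjusted OR with Wald CI and two-sided p.  ``groups`` maps
    each (possibly merged) row to the original bin indices it covers.
    """

    table: pd.DataFrame
    scheme: BinScheme
    groups: list[tuple[int, ...]]
    reference_group: int
    fit: LogisticFit
    design: DesignSpec = field(default_factory=DesignSpec)

    def rereference(self, new_reference_bin: int) -> "BinnedORTable":
        """Recompute crude and adjusted ORs against another original bin
        without refitting the logistic model."""
        new_group = next(
            (g for g, members in enumerate(self.groups) if new_reference_bin in members), None
        )
        if new_group is None:
            raise ValueError(f"bin {new_reference_bin} not present in this table")
        return _build_table(
            self.fit, self.table, self.scheme, self.groups, new_group, self.design
        )


def _merge_sparse(bin_idx: np.ndarray, y: np.ndarray, n_bins: int,
                  min_per_arm: int) -> list[tuple[int, ...]]:
    """Group original bins so every non-empty group has >= min_per_arm in
    both arms; sparse groups merge into the lower neighbour (group 0 merges
    upward into the next group)."""
    groups: list[list[int]] = [[i] for i in range(n_bins)]

    def counts(members):
        mask = np.isin(bin_idx, members)
        return int(y[mask].sum()), int((1 - y[mask]).sum())

    changed = True
    while changed and len(groups) > 1:
        changed = False
        for g in range(len(groups) - 1, -1, -1):
            ca, co = counts(groups[g])
            if ca + co == 0:
                continue
            if ca < min_per_arm or co < min_per_arm:
                tgt = g - 1 if g > 0 else g + 1
                warnings.warn(
                    f"exposure bin group {tuple(groups[g])} has sparse counts "
                    f"({ca} cases / {co} controls); merging with neighbour"
                )
                groups[tgt] = sorted(groups[tgt] + groups[g]) if tgt < g else sorted(
                    groups[g] + groups[tgt]
                )
                del groups[g]
                changed = True
                break
    # drop fully empty groups
    groups = [g for g in groups if sum(counts(g)) > 0]
    return [tuple(g) for g in groups]


def binned_or_table(
    cohort: pd.DataFrame,
    scheme: BinScheme = BinScheme(),
    design: DesignSpec = DesignSpec(),
    min_per_arm: int = MIN_PER_ARM,
) -> BinnedORTable:
    """Fit the binned dose-response table for a cohort.

    One logistic fit with indicator columns for every non-reference bin
    group (plus adjustment covariates and site intercepts) supplies the
    adjusted ORs; crude ORs are 2x2 cross-products against the reference.
    """
    y = cohort["is_case"].to_numpy(int)
    bin_idx = assign_bins(cohort["sir"].to_numpy(float), scheme)
    groups = _merge_sparse(bin_idx, y, scheme.n_bins, min_per_arm)
    ref_group = next(
        (g for g, members in enumerate(groups) if scheme.reference_bin in members), None
    )
    if ref_group is None:
        raise ValueError("reference bin is empty after merging")

    X, yv = encode_covariates(cohort, design)
    group_of = {b: g for g, members in enumerate(groups) for b in members}
    member_group = np.array([group_of[b] for b in bin_idx])
    for g in range(len(groups)):
        if g == ref_group:
            continue
        X[f"bin_g{g}"] = (member_group == g).astype(float)
    fit = fit_logistic(X, yv)

    # cache per-group summary stats on a scratch frame
    sir = cohort["sir"].to_numpy(float)
    rows = []
    for g, members in enumerate(groups):
        mask = np.isin(bin_idx, members)
        rows.append(
            {
                "n_cases": int(y[mask].sum()),
                "n_controls": int((1 - y[mask]).sum()),
                "mean_sir": float(sir[mask].mean()) if mask.any() else np.nan,
                "lo": scheme.edges[members[0]],
                "hi": scheme.edges[members[-1] + 1],
                "label": "+".join(scheme.label(b) for b in members)
                if len(members) > 1
                else scheme.label(members[0]),
            }
        )
    summary = pd.DataFrame(rows)
    return _build_table(fit, summary, scheme, groups, ref_group, design)


def _build_table(fit, summary, scheme, groups, ref_group, design) -> BinnedORTable:
    names = list(fit.params.index)
    z = norm.ppf(0.975)
    a_ref = summary.loc[ref_group, "n_cases"]
    b_ref = summary.loc[ref_group, "n_controls"]
    recs = []
    for g in range(len(groups)):
        row = summary.loc[g].to_dict()
        a, b = row["n_cases"], row["n_controls"]
        if g == ref_group:
            crude = (1.0, 1.0, 1.0)
            adj = (1.0, 1.0, 1.0, np.nan)
        else:
            orr = (a * b_ref) / (b * a_ref)
            se = np.sqrt(1 / a + 1 / b + 1 / a_ref + 1 / b_ref)
            crude = (orr, orr * np.exp(-z * se), orr * np.exp(z * se))
            c = np.zeros(fit.n_params)
            if f"bin_g{g}" in names:
                c[names.index(f"bin_g{g}")] = 1.0
            if f"bin_g{ref_group}" in names:
                c[names.index(f"bin_g{ref_group}")] = -1.0
            adj = wald_or_ci(fit, c)
        recs.append(
            {
                **row,
                "crude_or": crude[0],
                "crude_lo": crude[1],
                "crude_hi": crude[2],
                "adj_or": adj[0],
                "adj_lo": adj[1],
                "adj_hi": adj[2],
                "p_value": adj[3] if g != ref_group else np.nan,
                "is_reference": g == ref_group,
            }
        )
    table = pd.DataFrame(recs)
    return BinnedORTable(
        table=table,
        scheme=scheme,
        groups=list(groups),
        reference_group=ref_group,
        fit=fit,
        design=design,
    )
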