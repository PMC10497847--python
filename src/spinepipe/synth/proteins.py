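"""Synthetic MaxQuant-like protein intensity tables with planted effects.

Raw intensities follow a log-normal baseline per protein with multiplicative
mean-one log-normal sample noise, so the planted fold change of a protein
equals the ratio of its group mean intensities in expectation and exactly in
the zero-noise limit. A chosen fraction of proteins carries a planted fold
change (up or down) in one designated group; missing values are encoded as
NaN (never zero) with a per-group missing rate; unique-peptide counts are
drawn with a configurable singleton fraction so the two-peptide filter has
something to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..proteome import ProteinTable


@dataclass
class ProteinTableConfig:
    """Generator settings; defaults emulate a four-group, n=5 design."""

    n_proteins: int = 1200
    groups: list[tuple[str, int]] = field(
        default_factory=lambda: [("Y-CTR", 5), ("Y-BAY", 5), ("O-CTR", 5), ("O-BAY", 5)]
    )
    baseline_log10_mean: float = 7.0
    baseline_log10_sd: float = 0.8
    mw_log_mean: float = np.log(50.0)   # kDa, log-normal location
    mw_log_sd: float = 0.5
    fraction_dap: float = 0.1
    fold_range: tuple[float, float] = (1.2, 2.0)
    affected_group: str | None = None   # defaults to the last group
    up_fraction: float = 0.5
    missing_rate: float | dict[str, float] = 0.0
    singleton_fraction: float = 0.1     # proteins with a single unique peptide
    peptide_poisson_mean: float = 4.0
    noise_cv: float = 0.2               # within-group multiplicative CV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if not 0 <= self.fraction_dap <= 1:
            raise ValueError("fraction_dap must lie in [0, 1]")
        lo, hi = self.fold_range
        if lo < 1.0 or hi < lo:
            raise ValueError("planted fold changes must be >= 1")
        names = [g for g, _ in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")
        for g, n in self.groups:
            if n < 2:
                raise ValueError(f"group {g!r} needs at least 2 samples")
        if self.affected_group is None:
            self.affected_group = names[-1]
        if self.affected_group not in names:
            raise ValueError(f"affected_group {self.affected_group!r} unknown")

    def missing_rate_of(self, group: str) -> float:
        if isinstance(self.missing_rate, dict):
            return float(self.missing_rate.get(group, 0.0))
        return float(self.missing_rate)


def generate_protein_table(
    config: ProteinTableConfig,
) -> tuple[ProteinTable, pd.DataFrame]:
    """Generate a table plus the planted ground truth.

    Returns the ProteinTable and a truth frame indexed by protein id with
    columns ``planted`` (bool), ``fold`` (>= 1) and ``direction``
    ('up'/'down'/'none' relative to the affected group).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    ids = [f"P{i:05d}" for i in range(1, n + 1)]

    mw = np.exp(rng.normal(config.mw_log_mean, config.mw_log_sd, n))
    n_single = int(round(config.singleton_fraction * n))
    peptides = 2 + rng.poisson(config.peptide_poisson_mean, n)
    single_idx = rng.choice(n, size=n_single, replace=False)
    peptides[single_idx] = 1

    base = 10.0 ** rng.normal(config.baseline_log10_mean, config.baseline_log10_sd, n)

    n_dap = int(round(config.fraction_dap * n))
    dap_idx = rng.choice(n, size=n_dap, replace=False)
    folds = np.ones(n)
    lo, hi = config.fold_range
    folds[dap_idx] = lo if lo == hi else rng.uniform(lo, hi, n_dap)
    up = np.zeros(n, dtype=bool)
    up[dap_idx] = rng.uniform(size=n_dap) < config.up_fraction
    effect = np.where(up, folds, 1.0 / folds)
    effect[folds == 1.0] = 1.0

    # mean-one multiplicative log-normal noise at the requested CV
    sigma = np.sqrt(np.log1p(config.noise_cv**2))

    data = {"mw_kda": mw, "unique_peptides": peptides}
    groups_map: dict[str, str] = {}
    for g, n_samples in config.groups:
        miss = config.missing_rate_of(g)
        for k in range(1, n_samples + 1):
            col = f"{g}_{k}"
            groups_map[col] = g
            noise = np.exp(rng.normal(-sigma**2 / 2.0, sigma, n)) if sigma > 0 else 1.0
            vals = base * noise
            if g == config.affected_group:
                vals = vals * effect
            if miss > 0:
                vals = np.where(rng.uniform(size=n) < miss, np.nan, vals)
            data[col] = vals

    table = ProteinTable(
        data=pd.DataFrame(data, index=pd.Index(ids, name="protein_id")),
        groups=groups_map,
    )
    planted = np.zeros(n, dtype=bool)
    planted[dap_idx] = True
    truth = pd.DataFrame(
        {
            "planted": planted,
            "fold": folds,
            "direction": np.where(
                ~planted, "none", np.where(up, "up", "down")
            ),
        },
        index=pd.Index(ids, name="protein_id"),
    )
    return table, truth
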