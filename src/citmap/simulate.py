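"""Synthetic MALDI-TOF peak lists and expression matrices with known
ground truth.

The spectrum simulator digests a chain as trypsin would see it after
citrullination of a chosen set of arginines (blocked cleavage at every
planted site), emits the theoretical MH+ of each resulting peptide with
Gaussian m/z jitter, and sprinkles uniform decoy peaks.  The expression
simulator plants module-1/2/3 gene blocks on a log2 baseline with
per-donor Gaussian noise.  Both are bit-reproducible for a fixed config,
and both return a truth record sufficient to score any downstream stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .digest import DEFAULT_MAX_MISSED, ProteinChain, _cut_sites
from .masses import DEFAULT_CONSTANTS, MassConstants, ModificationState, peptide_mh
from .mapping import PeakList
from .modules import CONDITIONS, ExpressionMatrix, ModuleLabel

__all__ = [
    "SpectrumSimConfig",
    "SpectrumTruth",
    "ExpressionSimConfig",
    "ExpressionTruth",
    "simulate_spectrum",
    "simulate_expression",
]


@dataclass(frozen=True)
class SpectrumSimConfig:
    chain: ProteinChain
    true_sites: frozenset[int] = field(default_factory=frozenset)
    pgm: bool = True
    mz_jitter_sd: float = 0.05
    decoy_rate: float = 0.0  # expected decoys per true peak
    max_missed: int = DEFAULT_MAX_MISSED
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "true_sites", frozenset(self.true_sites))
        for pos in self.true_sites:
            if not (1 <= pos <= len(self.chain)) or self.chain.sequence[pos - 1] != "R":
                raise ValueError(f"planted site {pos} is not an R in the chain")
        if self.mz_jitter_sd < 0:
            raise ValueError("mz_jitter_sd must be non-negative")
        if self.decoy_rate < 0:
            raise ValueError("decoy_rate must be non-negative")


@dataclass(frozen=True)
class SpectrumTruth:
    chain_id: str
    true_sites: frozenset[int]
    true_peaks: tuple[dict, ...]  # one record per emitted non-decoy peak
    n_decoys: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "chain_id": self.chain_id,
                    "true_sites": sorted(self.true_sites),
                    "true_peaks": list(self.true_peaks),
                    "n_decoys": self.n_decoys,
                },
                fh,
                indent=2,
            )


def _modified_digest(
    chain: ProteinChain, sites: frozenset[int], max_missed: int
) -> list[tuple[int, int, frozenset[int], int]]:
    """Tryptic spans (start, end, cit subset, missed) of the chain after
    citrullination of ``sites``: planted R cut sites are blocked; every
    peptide carries exactly the planted sites inside its span."""
    cuts = [c for c in _cut_sites(chain.sequence) if c not in sites]
    bounds = [0] + cuts + [len(chain)]
    out = []
    for i, a in enumerate(bounds[:-1]):
        for missed, b in enumerate(bounds[i + 1 : i + 2 + max_missed]):
            span_sites = frozenset(p for p in sites if a < p <= b)
            out.append((a + 1, b, span_sites, missed))
    return out


def simulate_spectrum(
    config: SpectrumSimConfig, constants: MassConstants = DEFAULT_CONSTANTS
) -> tuple[PeakList, SpectrumTruth]:
    """One synthetic positive-mode spectrum of the citrullinated chain.

    Every tryptic peptide of the site-blocked digest (with up to
    ``max_missed`` miscleavages) contributes one peak at its theoretical
    MH+ (PGM applied to all citrullines when ``config.pgm``) plus
    N(0, mz_jitter_sd) jitter.  Decoy count ~ Poisson(decoy_rate x true
    peaks), positions uniform over the true m/z range.
    """
    rng = np.random.default_rng(config.seed)
    records = []
    mz = []
    for start, end, span_sites, missed in _modified_digest(
        config.chain, config.true_sites, config.max_missed
    ):
        state = ModificationState(span_sites, config.pgm and bool(span_sites))
        seq = config.chain.subseq(start, end)
        mh = peptide_mh(seq, state, start=start, constants=constants)
        obs = mh + rng.normal(0.0, config.mz_jitter_sd) if config.mz_jitter_sd else mh
        mz.append(obs)
        records.append(
            {
                "start": start,
                "end": end,
                "sequence": seq,
                "cit_positions": sorted(span_sites),
                "missed_cleavages": missed,
                "theoretical_mh": mh,
                "observed_mz": obs,
            }
        )
    n_decoys = int(rng.poisson(config.decoy_rate * len(mz))) if config.decoy_rate else 0
    if n_decoys:
        lo, hi = min(mz), max(mz)
        mz.extend(rng.uniform(lo, hi, size=n_decoys).tolist())
    intensity = rng.uniform(10.0, 1000.0, size=len(mz))
    peaks = PeakList(tuple(mz), tuple(intensity))
    truth = SpectrumTruth(
        chain_id=config.chain.chain_id,
        true_sites=config.true_sites,
        true_peaks=tuple(records),
        n_decoys=n_decoys,
    )
    return peaks, truth


# --- expression -------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionSimConfig:
    n_genes: int = 2000
    #: fractions of genes planted as module1 / module2 / module3; the
    #: remainder is unregulated background
    module_fractions: tuple[float, float, float] = (0.10, 0.05, 0.10)
    effect_log2: float = 2.0
    reversal_log2: float = 2.0
    donor_noise_sd: float = 0.3
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    n_donors: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.module_fractions) > 1.0 + 1e-9:
            raise ValueError("module fractions exceed 1")
        if any(f < 0 for f in self.module_fractions):
            raise ValueError("module fractions must be non-negative")
        if self.donor_noise_sd < 0:
            raise ValueError("donor_noise_sd must be non-negative")
        if self.n_donors < 2:
            raise ValueError("need at least 2 donors for concordance analysis")


@dataclass(frozen=True)
class ExpressionTruth:
    labels: tuple[ModuleLabel, ...]

    def as_dict(self) -> dict[str, str]:
        return {lab.gene: lab.module for lab in self.labels}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)


def simulate_expression(
    config: ExpressionSimConfig,
) -> tuple[ExpressionMatrix, ExpressionTruth]:
    """Log2 expression for vehicle / fibrinogen / citrullinated fibrinogen
    across donors, with planted module structure.

    module1: +effect under both fibrinogen conditions (up, citrullination
    indifferent).  module3: -effect under both (down, indifferent).
    module2: +-effect (direction random per gene) under fibrinogen,
    opposed by ``reversal_log2`` under citrullinated fibrinogen.
    Background: baseline only.  Independent N(0, donor_noise_sd) noise per
    gene x condition x donor.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    n1, n2, n3 = (int(round(f * n)) for f in config.module_fractions)
    modules = (["module1"] * n1 + ["module2"] * n2 + ["module3"] * n3)
    modules += ["none"] * (n - len(modules))
    genes = [f"G{i:05d}" for i in range(n)]
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    # planted per-gene effects on the fibrinogen and cit-fibrinogen conditions
    fib_eff = np.zeros(n)
    cit_eff = np.zeros(n)
    for i, mod in enumerate(modules):
        if mod == "module1":
            fib_eff[i] = config.effect_log2
            cit_eff[i] = config.effect_log2
        elif mod == "module3":
            fib_eff[i] = -config.effect_log2
            cit_eff[i] = -config.effect_log2
        elif mod == "module2":
            sign = 1.0 if rng.random() < 0.5 else -1.0
            fib_eff[i] = sign * config.effect_log2
            cit_eff[i] = sign * (config.effect_log2 - config.reversal_log2)
    donors = [f"donor{d + 1}" for d in range(config.n_donors)]
    data = {}
    for donor in donors:
        for cond in CONDITIONS:
            if cond == "vehicle":
                eff = np.zeros(n)
            elif cond == "fibrinogen":
                eff = fib_eff
            else:
                eff = cit_eff
            noise = (
                rng.normal(0.0, config.donor_noise_sd, size=n)
                if config.donor_noise_sd
                else np.zeros(n)
            )
            data[(cond, donor)] = baseline + eff + noise
    values = pd.DataFrame(data, index=pd.Index(genes, name="gene"))
    values.columns = pd.MultiIndex.from_tuples(values.columns, names=["condition", "donor"])
    truth = ExpressionTruth(tuple(ModuleLabel(g, m) for g, m in zip(genes, modules)))
    return ExpressionMatrix(values), truth
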