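"""Assignment accuracy versus marker-panel size.

Simulates genotypes on a known ("true") pedigree for panels of varying
size drawn from the real marker set, refits the pedigree with the
protocol's breeder-restriction / main-fit / averaging stages, and
scores how many parentage assignments are made confidently and how
many of those are correct.  Panels larger than the real 17-locus set
are composed of the full set plus a second group resampled without
replacement; duplicated loci are simulated as independent markers
sharing the source locus' allele frequencies (the only reading under
which duplication adds information).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .error_model import ErrorRates, simulate_observation
from .genodata import AlleleFrequencyTable
from .pedigree_core import UNKNOWN, UNSAMPLED, Pedigree
from .protocol import (
    ProtocolConfig,
    StudyData,
    step3_possible_breeders,
    step4_main_fit,
    step5_average,
)
from .synthetic_data import simulate_true_genotypes

__all__ = [
    "PanelSpec",
    "AssignmentScore",
    "subsample_panel",
    "panel_frequency_table",
    "simulate_genotypes_on_pedigree",
    "evaluate_assignments",
    "panel_power_experiment",
    "summarize_scores",
]

MAX_PANEL = 34


@dataclass(frozen=True)
class PanelSpec:
    """A marker panel: panel locus ids mapped to their source loci."""

    size: int
    loci: tuple[tuple[str, str], ...]  # (panel id, source locus id)
    replicate: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size != len(self.loci):
            raise ValueError("size does not match locus list")
        panel_ids = [p for p, _ in self.loci]
        if len(set(panel_ids)) != len(panel_ids):
            raise ValueError("panel ids must be unique")


def subsample_panel(
    loci: Sequence[str], size: int, seed: int = 0, replicate: int = 1
) -> PanelSpec:
    """Sample a panel of ``size`` loci without replacement within groups.

    size <= 17: a plain sample without replacement; 17 < size <= 34:
    the full set plus (size - 17) loci resampled without replacement
    (duplicates get a ``#2`` suffix); size = 34 duplicates every locus.
    """
    loci = list(loci)
    n = len(loci)
    if size < 1:
        raise ValueError("panel size must be >= 1")
    if size > 2 * n or size > MAX_PANEL:
        raise ValueError(f"panel size {size} exceeds the design ceiling")
    rng = np.random.default_rng(seed)
    if size <= n:
        chosen = sorted(rng.choice(loci, size=size, replace=False).tolist())
        pairs = tuple((loc, loc) for loc in chosen)
    else:
        extra = sorted(rng.choice(loci, size=size - n, replace=False).tolist())
        pairs = tuple((loc, loc) for loc in sorted(loci)) + tuple(
            (f"{loc}#2", loc) for loc in extra
        )
    return PanelSpec(size=size, loci=pairs, replicate=replicate, seed=seed)


def panel_frequency_table(
    panel: PanelSpec, freqs: AlleleFrequencyTable
) -> AlleleFrequencyTable:
    """Frequency table for the panel; duplicates share source frequencies."""
    return AlleleFrequencyTable(
        {pid: freqs.locus_freqs(src) for pid, src in panel.loci}
    )


def _panel_rates(panel: PanelSpec, rates: ErrorRates) -> ErrorRates:
    out = ErrorRates(rates.default_e1, rates.default_e2)
    for (loc, sc), (e1, e2) in rates.per_locus.items():
        for pid, src in panel.loci:
            if src == loc:
                out.set(pid, sc, e1, e2)
    return out


def simulate_genotypes_on_pedigree(
    pedigree: Pedigree,
    freqs: AlleleFrequencyTable,
    rates: ErrorRates,
    panel: PanelSpec | None = None,
    seed: int = 0,
    source_class: str = "SCAT",
) -> tuple[dict[str, dict[str, tuple[str, str] | None]], AlleleFrequencyTable, ErrorRates]:
    """Observed individual genotypes simulated down a known pedigree.

    Founders are drawn from Hardy-Weinberg, descendants by Mendelian
    segregation, and each individual's genotype is then passed once
    through the error model.  Returns (observed genotypes, the panel
    frequency table, the panel error rates).
    """
    if panel is None:
        panel = PanelSpec(
            size=len(freqs.loci),
            loci=tuple((loc, loc) for loc in freqs.loci),
        )
    pfreqs = panel_frequency_table(panel, freqs)
    prates = _panel_rates(panel, rates)
    rng = np.random.default_rng(seed)
    true = simulate_true_genotypes(pedigree, pfreqs, rng)
    observed: dict[str, dict[str, tuple[str, str] | None]] = {}
    for ind in sorted(true):
        observed[ind] = {
            loc: simulate_observation(true[ind][loc], loc, pfreqs, prates, rng, source_class)
            for loc in pfreqs.loci
        }
    return observed, pfreqs, prates


@dataclass(frozen=True)
class AssignmentScore:
    panel_size: int
    replicate: int
    n_confident: int
    n_confident_correct: int
    n_assignable: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_confident_correct <= self.n_confident <= self.n_assignable:
            raise ValueError("inconsistent assignment counts")

    @property
    def fp_fraction(self) -> float:
        if self.n_confident == 0:
            return 0.0
        return 1.0 - self.n_confident_correct / self.n_confident


def evaluate_assignments(
    fitted: Pedigree,
    truth: Pedigree,
    threshold: float = 0.80,
    sampled: "set[str] | None" = None,
) -> AssignmentScore:
    """Score a fitted pedigree against the generating truth.

    Every individual exposes two assignment slots (dam, sire).  A slot
    is confident when its support exceeds ``threshold`` and correct
    when it names the true parent; an UNSAMPLED assignment is correct
    only when the true parent lies outside the sampled set.
    """
    if set(fitted.parents) != set(truth.parents):
        raise ValueError("fitted and true pedigrees cover different individuals")
    sampled = set(truth.parents) if sampled is None else sampled
    n_conf = n_corr = 0
    for o in fitted.parents:
        fd, fs = fitted.parents[o]
        td, ts = truth.parents[o]
        dp, sp = fitted.link_prob.get(o, (0.0, 0.0))
        for assigned, true_p, conf in ((fd, td, dp), (fs, ts, sp)):
            if assigned == UNKNOWN or conf <= threshold:
                continue
            n_conf += 1
            if assigned == UNSAMPLED:
                correct = true_p in (UNSAMPLED, UNKNOWN) or true_p not in sampled
            else:
                correct = assigned == true_p
            n_corr += int(correct)
    return AssignmentScore(
        panel_size=0,
        replicate=0,
        n_confident=n_conf,
        n_confident_correct=n_corr,
        n_assignable=2 * len(fitted.parents),
    )


def _fit_steps_3_to_5(
    genotypes: Mapping[str, Mapping[str, tuple[str, str] | None]],
    sexes: Mapping[str, str],
    freqs: AlleleFrequencyTable,
    rates: ErrorRates,
    config: ProtocolConfig,
    seed: int,
    detection_dates: Mapping[str, object] | None = None,
    fixed_breeders: "set[str] | None" = None,
) -> Pedigree:
    data = StudyData(
        genotypes=dict(genotypes),
        sexes=dict(sexes),
        freqs=freqs,
        detection_dates=dict(detection_dates or {}),
    )
    if fixed_breeders is not None:
        breeders = set(fixed_breeders)
    else:
        breeders, _ = step3_possible_breeders(data, rates, config, seed)
    if not breeders:
        breeders = set(data.individuals)
    runs = step4_main_fit(data, rates, breeders, config, seed + 500)
    return step5_average(runs, config)


def panel_power_experiment(
    true_pedigree: Pedigree,
    freqs: AlleleFrequencyTable,
    rates: ErrorRates,
    sizes: Sequence[int] = (5, 10, 17, 20, 25, 30, 34),
    reps: int = 10,
    config: ProtocolConfig = ProtocolConfig(),
    seed: int = 0,
    threshold: float = 0.80,
    detection_dates: Mapping[str, object] | None = None,
    fixed_breeders: "set[str] | None" = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """Simulate-and-refit across panel sizes.

    For each (size, replicate): draw a panel, simulate genotypes on the
    true pedigree, refit with protocol steps 3-5 at the given error
    rates, and score confident/correct assignments.  With
    ``fixed_breeders`` the possible-parent set is held fixed across
    replicates (the design under which the accuracy of an existing fit
    is probed: the same frequencies, error rates and possible parents,
    only the genotypes resimulated); otherwise step 3 is re-run per
    replicate.  Returns (per-replicate table, per-size summary with
    mean +/- se, slope summary for the 17->20 contrast and the 20->34
    range).
    """
    sexes = dict(true_pedigree.sexes)
    rows: list[dict] = []
    run = 0
    for size in sizes:
        for rep in range(1, reps + 1):
            run += 1
            panel = subsample_panel(freqs.loci, size, seed=seed + 13 * run, replicate=rep)
            observed, pfreqs, prates = simulate_genotypes_on_pedigree(
                true_pedigree, freqs, rates, panel, seed=seed + 13 * run + 1
            )
            fitted = _fit_steps_3_to_5(
                observed, sexes, pfreqs, prates, config,
                seed=seed + 13 * run + 2, detection_dates=detection_dates,
                fixed_breeders=fixed_breeders,
            )
            score = evaluate_assignments(fitted, true_pedigree, threshold)
            rows.append(
                {
                    "size": size,
                    "replicate": rep,
                    "n_confident": score.n_confident,
                    "n_confident_correct": score.n_confident_correct,
                    "n_assignable": score.n_assignable,
                    "fp_fraction": score.fp_fraction,
                }
            )
    table = pd.DataFrame(rows)
    summary = summarize_scores(table)
    slopes = _slope_summary(table)
    return table, summary, slopes


def summarize_scores(table: pd.DataFrame) -> pd.DataFrame:
    g = table.groupby("size")
    out = pd.DataFrame(
        {
            "mean_confident": g["n_confident"].mean(),
            "se_confident": g["n_confident"].sem(),
            "mean_correct": g["n_confident_correct"].mean(),
            "se_correct": g["n_confident_correct"].sem(),
            "mean_fp_fraction": g["fp_fraction"].mean(),
        }
    )
    return out.reset_index()


def _slope_summary(table: pd.DataFrame) -> dict[str, float]:
    """Linear trends in correct-confident counts.

    ``slope_17_20_per_marker``: OLS coefficient of correct count on
    panel size over the {17, 20} contrast (per added marker);
    ``contrast_17_20`` is the difference of means.  ``slope_20_34`` is
    the per-marker OLS slope over sizes in [20, 34].  Entries are NaN
    when the relevant sizes are absent.
    """
    out: dict[str, float] = {}
    sub = table[table["size"].isin([17, 20])]
    if sub["size"].nunique() == 2:
        res = stats.linregress(sub["size"], sub["n_confident_correct"])
        out["slope_17_20_per_marker"] = float(res.slope)
        out["slope_17_20_stderr"] = float(res.stderr)
        means = sub.groupby("size")["n_confident_correct"].mean()
        out["contrast_17_20"] = float(means.loc[20] - means.loc[17])
    else:
        out["slope_17_20_per_marker"] = float("nan")
        out["slope_17_20_stderr"] = float("nan")
        out["contrast_17_20"] = float("nan")
    sub = table[(table["size"] >= 20) & (table["size"] <= 34)]
    if sub["size"].nunique() >= 2:
        res = stats.linregress(sub["size"], sub["n_confident_correct"])
        out["slope_20_34"] = float(res.slope)
        out["slope_20_34_stderr"] = float(res.stderr)
    else:
        out["slope_20_34"] = float("nan")
        out["slope_20_34_stderr"] = float("nan")
    return out
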