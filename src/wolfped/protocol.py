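"""The six-step pedigree-estimation protocol.

Orchestrates the genotype data, error model and MCMC sampler:

1. **Preliminary pedigree** — one chain at fixed error rates
   (E1 = 4%, E2 = 2.2%); links above 90% confidence become the input
   pedigree for error estimation.
2. **Error rates** — per-locus (E1, E2) posteriors with the partial
   pedigree fixed, combining repeat-sample concordance with the fixed
   parent-offspring links; chains initialised at 0.1.
3. **Possible breeders** — 20 independent chains at the estimated
   rates; individuals appearing in at least 5% of parentage slots
   across the modal pedigrees are retained as candidate parents.
4. **Main fit** — 20 independent chains with candidates restricted to
   the possible breeders.
5. **Averaging** — per offspring, the mean support of each parent pair
   across the 20 modal pedigrees (absent in a run counts 0); the
   highest-mean pair is assigned.
6. **Consistency** — temporal (minimum breeding age), single-offspring
   medium-confidence pairs and one-litter-per-territory-year checks,
   plus the both/only-mother/only-father/neither summary; documented
   manual corrections are applied through a ledger, never silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date
from typing import Mapping, Sequence

import numpy as np

from .error_model import ErrorRates
from .genodata import AlleleFrequencyTable
from .pedigree_core import (
    UNKNOWN,
    UNSAMPLED,
    CohortInfo,
    Pedigree,
    infer_birth_years,
    is_legal,
)
from .pedigree_mcmc import (
    MCMCSettings,
    PosteriorPedigree,
    Priors,
    build_candidates,
    modal_pedigree,
    sample_error_rates,
    sample_pedigree,
)

__all__ = [
    "ProtocolConfig",
    "StudyData",
    "CorrectionEntry",
    "CorrectionsLedger",
    "ProtocolResult",
    "step1_preliminary",
    "step2_error_rates",
    "step3_possible_breeders",
    "step4_main_fit",
    "step5_average",
    "step6_consistency",
    "apply_corrections",
    "run_protocol",
]


@dataclass
class ProtocolConfig:
    """All protocol stage settings.

    Defaults are the full production settings; :meth:`desk_scale`
    returns a configuration with shorter chains and fewer runs for
    interactive work and the packaged recovery experiments.
    """

    # step 1
    step1_iterations: int = 20000
    step1_burn_in: int = 2000
    step1_e1: float = 0.04
    step1_e2: float = 0.022
    # step 2
    step2_iterations: int = 3000
    step2_burn_in: int = 500
    step2_init: float = 0.1
    step2_confidence: float = 0.90
    tissue_e1: float = 0.04
    tissue_e2: float = 0.022
    # step 3
    step3_runs: int = 20
    step3_iterations: int = 25000
    step3_burn_in: int = 1000
    breeder_threshold: float = 0.05  # used by the "pooled" / "per_run" rules
    breeder_min_mean: float = 1.0  # used by the "mean_assignments" rule
    breeder_rule: str = "mean_assignments"  # or "pooled" | "per_run"
    step3_stages: int = 2  # rescreen once with candidates restricted to stage-1 set
    stage2_min_mean: float = 1.5
    # candidate parents must be first observed before the offspring
    require_prior_detection: bool = True
    # step 4
    step4_runs: int = 20
    step4_iterations: int = 30000
    step4_burn_in: int = 3000
    # step 5
    absent_counts_zero: bool = True
    # shared
    thinning: int = 2
    max_mismatch_loci: int = 4
    priors: Priors = field(default_factory=Priors)
    # confidence vocabulary
    confident: float = 0.80
    high: float = 0.90
    very_high: float = 0.95
    medium_band: tuple[float, float] = (0.70, 0.80)

    def __post_init__(self) -> None:
        for t in (self.confident, self.high, self.very_high, self.breeder_threshold):
            if not 0 < t < 1:
                raise ValueError(f"threshold out of (0,1): {t}")
        if self.step3_runs < 1 or self.step4_runs < 1:
            raise ValueError("runs must be >= 1")

    @classmethod
    def desk_scale(cls) -> "ProtocolConfig":
        """Reduced chains/runs for the packaged recovery experiments."""
        return cls(
            step1_iterations=4000,
            step1_burn_in=800,
            step2_iterations=1500,
            step2_burn_in=400,
            step3_runs=6,
            step3_iterations=2500,
            step3_burn_in=400,
            step4_runs=12,
            step4_iterations=3000,
            step4_burn_in=500,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["priors"] = asdict(self.priors)
        return d


@dataclass
class StudyData:
    """Consensus-genotyped individuals plus the inputs the sampler needs."""

    genotypes: dict[str, dict[str, tuple[str, str] | None]]
    sexes: dict[str, str]
    freqs: AlleleFrequencyTable
    detection_dates: dict[str, date] = field(default_factory=dict)
    source_class: dict[str, str] = field(default_factory=dict)
    cohorts: CohortInfo | None = None
    # per-sample replicate calls, for error-rate estimation
    replicate_states: dict[str, dict[str, list[tuple[str, str] | None]]] = field(
        default_factory=dict
    )
    sample_to_individual: dict[str, str] = field(default_factory=dict)

    @property
    def individuals(self) -> list[str]:
        return sorted(self.genotypes)

    @classmethod
    def from_truth(cls, truth) -> "StudyData":
        """Assemble study data from a synthetic TruthPackage using the
        true sample-individual map (identification is exercised
        separately); per-individual consensus by majority over samples."""
        from .genodata import _majority_consensus

        by_ind: dict[str, list[dict]] = {}
        consensus = truth.consensus_by_sample()
        for sid, geno in consensus.items():
            by_ind.setdefault(truth.sample_individual[sid], []).append(geno)
        loci = truth.freqs.loci
        genotypes = {
            ind: _majority_consensus(genos, loci) for ind, genos in by_ind.items()
        }
        demo = truth.demography
        first_seen: dict[str, date] = {}
        src_count: dict[str, dict[str, int]] = {}
        for s in truth.samples:
            ind = truth.sample_individual[s.sample_id]
            if ind not in first_seen or s.date < first_seen[ind]:
                first_seen[ind] = s.date
            src_count.setdefault(ind, {}).setdefault(s.source_class, 0)
            src_count[ind][s.source_class] += 1
        source_class = {
            ind: max(c.items(), key=lambda kv: kv[1])[0] for ind, c in src_count.items()
        }
        return cls(
            genotypes=genotypes,
            sexes={i: demo.sexes[i] for i in genotypes},
            freqs=truth.freqs,
            detection_dates=first_seen,
            source_class=source_class,
            replicate_states=truth.replicate_states(),
            sample_to_individual=dict(truth.sample_individual),
        )


def _protocol_candidates(
    data: StudyData,
    config: ProtocolConfig,
    allowed: "Sequence[str] | None" = None,
) -> dict[str, tuple[list[str], list[str]]]:
    """Exclusion-filtered candidate sets, optionally restricted to the
    possible breeders and to individuals first observed before the
    offspring (the data ordering that makes later-observed individuals
    the offspring of earlier-observed ones)."""
    cands = build_candidates(
        data.genotypes,
        data.sexes,
        config.max_mismatch_loci,
        data.cohorts,
        allowed=allowed,
    )
    if config.require_prior_detection and data.detection_dates:
        dd = data.detection_dates

        def _earlier(c: str, o: str) -> bool:
            if c not in dd or o not in dd:
                return True  # no information: keep
            return dd[c] < dd[o]

        cands = {
            o: (
                [d for d in ds if _earlier(d, o)],
                [s for s in ss if _earlier(s, o)],
            )
            for o, (ds, ss) in cands.items()
        }
    return cands


def _settings(
    iterations: int, burn_in: int, config: ProtocolConfig, seed: int
) -> MCMCSettings:
    return MCMCSettings(
        iterations=iterations,
        burn_in=burn_in,
        thinning=config.thinning,
        seed=seed,
        max_mismatch_loci=config.max_mismatch_loci,
    )


# ---------------------------------------------------------------------------
# Steps
# ---------------------------------------------------------------------------


def step1_preliminary(
    data: StudyData, config: ProtocolConfig, seed: int = 0
) -> tuple[Pedigree, Pedigree, PosteriorPedigree]:
    """Preliminary pedigree at fixed error rates.

    Returns (modal pedigree, the >90%-confidence partial pedigree used
    as the error-estimation input, posterior).
    """
    rates = ErrorRates(config.step1_e1, config.step1_e2)
    post = sample_pedigree(
        data.genotypes,
        data.sexes,
        data.freqs,
        rates,
        priors=config.priors,
        settings=_settings(config.step1_iterations, config.step1_burn_in, config, seed),
        cohorts=data.cohorts,
        detection_dates=data.detection_dates,
        candidates=_protocol_candidates(data, config),
        source_class=data.source_class,
    )
    modal = modal_pedigree(post)
    partial = Pedigree(sexes=dict(modal.sexes))
    for o in modal.parents:
        d, s = modal.parents[o]
        dp, sp = modal.link_prob.get(o, (0.0, 0.0))
        partial.parents[o] = (
            d if dp > config.step2_confidence else UNKNOWN,
            s if sp > config.step2_confidence else UNKNOWN,
        )
    return modal, partial, post


def step2_error_rates(
    data: StudyData,
    partial_pedigree: Pedigree,
    config: ProtocolConfig,
    seed: int = 0,
) -> tuple[ErrorRates, dict]:
    """Per-locus (E1, E2) posteriors with the partial pedigree fixed.

    Scat-class rates per locus come from the posterior means; the
    tissue/secretion class keeps its constants (too few repeat tissue
    samples to estimate from).  Loci without informative replicates
    fall back to the prior and are flagged in the summary.
    """
    rates, summaries = sample_error_rates(
        data.replicate_states,
        data.freqs,
        fixed_pedigree=partial_pedigree,
        individual_genotypes=data.genotypes,
        sample_to_individual=data.sample_to_individual,
        priors=config.priors,
        iterations=config.step2_iterations,
        burn_in=config.step2_burn_in,
        init=config.step2_init,
        seed=seed,
        source_class="SCAT",
    )
    for loc in data.freqs.loci:
        rates.set(loc, "TISSUE_SECRETION", config.tissue_e1, config.tissue_e2)
    return rates, summaries


@dataclass
class ModalRun:
    """One chain's modal pedigree with its posterior supports."""

    pedigree: Pedigree
    pair_support: dict[str, float]  # support of the pair kept in the pedigree
    dam_marginal: dict[str, dict[str, float]]
    sire_marginal: dict[str, dict[str, float]]


def _run_chains(
    data: StudyData,
    rates: ErrorRates,
    config: ProtocolConfig,
    runs: int,
    iterations: int,
    burn_in: int,
    seed: int,
    candidates=None,
) -> list[ModalRun]:
    out = []
    for r in range(runs):
        post = sample_pedigree(
            data.genotypes,
            data.sexes,
            data.freqs,
            rates,
            priors=config.priors,
            settings=_settings(iterations, burn_in, config, seed + r),
            cohorts=data.cohorts,
            detection_dates=data.detection_dates,
            candidates=candidates,
            source_class=data.source_class,
        )
        ped = modal_pedigree(post)
        pair_conf: dict[str, float] = {}
        dam_m: dict[str, dict[str, float]] = {}
        sire_m: dict[str, dict[str, float]] = {}
        for o in post.offspring:
            pair_conf[o] = post.pair_probabilities(o).get(ped.parents[o], 0.0)
            dam_m[o], sire_m[o] = post.marginals(o)
        out.append(ModalRun(ped, pair_conf, dam_m, sire_m))
    return out


def step3_possible_breeders(
    data: StudyData,
    rates: ErrorRates,
    config: ProtocolConfig,
    seed: int = 0,
) -> tuple[set[str], list[Pedigree]]:
    """Identify possible breeders from repeated modal pedigrees.

    Default rule ``mean_assignments``: an individual qualifies when it
    averages at least ``breeder_min_mean`` modal parentage assignments
    per run — i.e. it is consistently fitted as somebody's parent.
    With ``step3_stages`` = 2 the screen is repeated once with
    candidates restricted to the first-pass set (and the stricter
    ``stage2_min_mean``), which sharpens the set by forcing impostor
    relatives to compete directly with the true parents.  The
    fraction-of-slots readings are available as ``"pooled"``
    (appearances / (2 x n x runs) >= threshold) and ``"per_run"``
    (>= threshold of slots within any single run); note both exclude
    any breeder with fewer than threshold x 2n offspring outright.
    """
    n_off = len(data.genotypes)
    slots_per_run = 2 * n_off
    allowed: "list[str] | None" = None
    breeders: set[str] = set()
    pedigrees: list[Pedigree] = []
    for stage in range(max(1, config.step3_stages)):
        chains = _run_chains(
            data,
            rates,
            config,
            config.step3_runs,
            config.step3_iterations,
            config.step3_burn_in,
            seed + 101 * stage,
            candidates=_protocol_candidates(data, config, allowed),
        )
        pedigrees = [run.pedigree for run in chains]
        counts_pooled: dict[str, int] = {}
        per_run_sets: set[str] = set()
        for run in chains:
            counts_run: dict[str, int] = {}
            for o, (d, s) in run.pedigree.parents.items():
                for p in (d, s):
                    if p not in (UNSAMPLED, UNKNOWN):
                        counts_run[p] = counts_run.get(p, 0) + 1
                        counts_pooled[p] = counts_pooled.get(p, 0) + 1
            per_run_sets |= {
                p
                for p, c in counts_run.items()
                if c / slots_per_run >= config.breeder_threshold
            }
        if config.breeder_rule == "mean_assignments":
            min_mean = config.breeder_min_mean if stage == 0 else config.stage2_min_mean
            breeders = {
                p
                for p, c in counts_pooled.items()
                if c / len(chains) >= min_mean
            }
        elif config.breeder_rule == "pooled":
            total = slots_per_run * len(chains)
            breeders = {
                p
                for p, c in counts_pooled.items()
                if c / total >= config.breeder_threshold
            }
        elif config.breeder_rule == "per_run":
            breeders = per_run_sets
        else:
            raise ValueError(f"unknown breeder_rule {config.breeder_rule!r}")
        if not breeders:
            break
        allowed = sorted(breeders)
    return breeders, pedigrees


def step4_main_fit(
    data: StudyData,
    rates: ErrorRates,
    breeders: set[str],
    config: ProtocolConfig,
    seed: int = 0,
) -> list[ModalRun]:
    """Repeated main fits with candidates restricted to possible breeders."""
    if not breeders:
        raise ValueError("empty possible-breeder set")
    candidates = _protocol_candidates(data, config, allowed=sorted(breeders))
    return _run_chains(
        data,
        rates,
        config,
        config.step4_runs,
        config.step4_iterations,
        config.step4_burn_in,
        seed,
        candidates=candidates,
    )


def step5_average(
    modal_runs: "Sequence[ModalRun]",
    config: ProtocolConfig = ProtocolConfig(),
) -> Pedigree:
    """Average parent-pair support across the repeated main fits.

    Per offspring, each pair observed in any run's modal pedigree gets
    the mean of its per-run support, a run where it is absent
    contributing 0 (or, with ``absent_counts_zero`` False, the mean
    over runs where it appears); the maximum-mean pair wins, ties
    toward UNSAMPLED then lexicographic.  The per-link confidence of
    the winning dam and sire is the mean of their *marginal* posterior
    supports across the runs (assignments are reported per parent, so a
    parent that is certain while its mate is split keeps its own
    support).  The output is legality-checked.
    """
    if not modal_runs:
        raise ValueError("no modal pedigrees to average")
    n_runs = len(modal_runs)
    offspring = sorted(modal_runs[0].pedigree.parents)
    sexes = dict(modal_runs[0].pedigree.sexes)
    out = Pedigree(sexes=sexes)
    for o in offspring:
        support: dict[tuple[str, str], list[float]] = {}
        for run in modal_runs:
            pair = run.pedigree.parents.get(o)
            if pair is None:
                continue
            support.setdefault(pair, []).append(run.pair_support.get(o, 0.0))
        means = {
            pair: (sum(v) / n_runs if config.absent_counts_zero else sum(v) / len(v))
            for pair, v in support.items()
        }
        best = max(means.values())
        tied = sorted(
            [k for k, v in means.items() if v == best],
            key=lambda k: (-(k[0] == UNSAMPLED) - (k[1] == UNSAMPLED), k),
        )
        pair = tied[0]
        out.parents[o] = pair
        dam_conf = sum(r.dam_marginal.get(o, {}).get(pair[0], 0.0) for r in modal_runs) / n_runs
        sire_conf = sum(r.sire_marginal.get(o, {}).get(pair[1], 0.0) for r in modal_runs) / n_runs
        out.link_prob[o] = (dam_conf, sire_conf)
    ok, why = is_legal(out)
    if not ok:
        out.flags.append(f"ILLEGAL_AVERAGE:{why}")
        # fall back to greedy repair ordered by confidence
        order = sorted(offspring, key=lambda o: -out.link_prob[o][0])
        repaired = Pedigree(sexes=sexes)
        for o in order:
            pair = out.parents[o]
            repaired.parents[o] = pair
            if not is_legal(repaired)[0]:
                repaired.parents[o] = (UNSAMPLED, UNSAMPLED)
            repaired.link_prob[o] = out.link_prob[o]
        repaired.parents = {o: repaired.parents[o] for o in offspring}
        repaired.flags = list(out.flags) + ["REPAIRED"]
        return repaired
    return out


@dataclass
class ConsistencyReport:
    anachronisms: list[str]
    single_offspring_pairs: list[str]
    territory_conflicts: list[str]
    counts: dict[str, int]  # both / only_mother / only_father / neither

    @property
    def n_flags(self) -> int:
        return (
            len(self.anachronisms)
            + len(self.single_offspring_pairs)
            + len(self.territory_conflicts)
        )


def step6_consistency(
    pedigree: Pedigree,
    config: ProtocolConfig = ProtocolConfig(),
    detection_dates: Mapping[str, date] | None = None,
    cohorts: CohortInfo | None = None,
    territories: Mapping[str, tuple[object, int]] | None = None,
) -> ConsistencyReport:
    """Biological-sensibility checks and the assignment summary.

    * ANACHRONISM: a sampled parent that would have been younger than
      the minimum breeding age (or already dead) at the offspring's
      inferred birth year.
    * SINGLE_OFFSPRING_PAIR: a medium-confidence (70-80%) parent pair
      appearing as parents of exactly one individual (established pairs
      produce litters of several cubs).
    * TERRITORY_CONFLICT: two different pairs credited with a litter in
      the same territory-year (``territories`` maps offspring ->
      (territory label, litter year)).
    * counts: individuals with both / only mother / only father /
      neither parent assigned above the confident threshold.
    """
    if cohorts is None:
        cohorts = infer_birth_years(pedigree, dict(detection_dates or {}))
    lo, hi = config.medium_band

    anach: list[str] = []
    for o, (d, s) in pedigree.parents.items():
        ob = cohorts.effective_birth(o)
        if ob is None:
            continue
        for role, p in (("dam", d), ("sire", s)):
            if p in (UNSAMPLED, UNKNOWN):
                continue
            pb = cohorts.effective_birth(p)
            if pb is not None and pb + cohorts.min_breeding_age > ob:
                anach.append(
                    f"{role} {p} (born ~{pb}) too young for {o} (born ~{ob})"
                )
            dy = cohorts.death_year.get(p)
            if dy is not None and dy < ob:
                anach.append(f"{role} {p} dead ({dy}) before birth of {o} (~{ob})")

    pair_offspring: dict[tuple[str, str], list[str]] = {}
    for o, pair in pedigree.parents.items():
        if UNKNOWN in pair:
            continue
        pair_offspring.setdefault(pair, []).append(o)
    single: list[str] = []
    for pair, offs in pair_offspring.items():
        if len(offs) != 1:
            continue
        o = offs[0]
        dp, sp = pedigree.link_prob.get(o, (1.0, 1.0))
        conf = min(dp, sp)
        if lo <= conf <= hi:
            single.append(f"pair {pair} assigned only {o} at confidence {conf:.2f}")

    terr: list[str] = []
    if territories:
        litters: dict[tuple[object, int], set[tuple[str, str]]] = {}
        for o, (t, y) in territories.items():
            pair = pedigree.parents.get(o)
            if pair is None or UNKNOWN in pair:
                continue
            litters.setdefault((t, y), set()).add(pair)
        for (t, y), pairs in sorted(litters.items(), key=str):
            if len(pairs) > 1:
                terr.append(f"territory {t} year {y}: {len(pairs)} breeding pairs")

    counts = {"both": 0, "only_mother": 0, "only_father": 0, "neither": 0}
    for o in pedigree.parents:
        d, s = pedigree.parents[o]
        dp, sp = pedigree.link_prob.get(o, (0.0, 0.0))
        dam_ok = d != UNKNOWN and dp > config.confident
        sire_ok = s != UNKNOWN and sp > config.confident
        if dam_ok and sire_ok:
            counts["both"] += 1
        elif dam_ok:
            counts["only_mother"] += 1
        elif sire_ok:
            counts["only_father"] += 1
        else:
            counts["neither"] += 1
    return ConsistencyReport(anach, single, terr, counts)


# ---------------------------------------------------------------------------
# Corrections ledger
# ---------------------------------------------------------------------------


@dataclass
class CorrectionEntry:
    offspring: str
    field: str  # "dam" | "sire"
    old_value: str
    new_value: str
    reason: str  # ANACHRONISM | SINGLE_OFFSPRING_PAIR | TERRITORY_CONFLICT | CONFIRMED
    note: str = ""

    REASONS = (
        "ANACHRONISM",
        "SINGLE_OFFSPRING_PAIR",
        "TERRITORY_CONFLICT",
        "CONFIRMED",
    )

    def __post_init__(self) -> None:
        if self.field not in ("dam", "sire"):
            raise ValueError(f"field must be dam|sire, got {self.field!r}")
        if self.reason not in self.REASONS:
            raise ValueError(f"unknown reason {self.reason!r}")


@dataclass
class CorrectionsLedger:
    entries: list[CorrectionEntry] = field(default_factory=list)

    def add(self, *args, **kwargs) -> None:
        self.entries.append(CorrectionEntry(*args, **kwargs))


def apply_corrections(
    pedigree: Pedigree, ledger: CorrectionsLedger
) -> tuple[Pedigree, dict[str, int]]:
    """Apply documented manual corrections in order.

    CONFIRMED entries change nothing (they record that a low-confidence
    link was accepted).  Any edit that would create an ancestry cycle
    or sex-role violation is rejected with an error.  Returns the final
    pedigree and a summary {"altered": n, "confirmed": n}.
    """
    out = pedigree.copy()
    altered = confirmed = 0
    for e in ledger.entries:
        if e.offspring not in out.parents:
            raise ValueError(f"correction references unknown offspring {e.offspring!r}")
        d, s = out.parents[e.offspring]
        current = d if e.field == "dam" else s
        if e.reason == "CONFIRMED":
            confirmed += 1
            continue
        if current != e.old_value:
            raise ValueError(
                f"{e.offspring}.{e.field} is {current!r}, ledger expected {e.old_value!r}"
            )
        trial = out.copy()
        if e.field == "dam":
            trial.parents[e.offspring] = (e.new_value, s)
        else:
            trial.parents[e.offspring] = (d, e.new_value)
        ok, why = is_legal(trial)
        if not ok:
            raise ValueError(f"correction for {e.offspring} rejected: {why}")
        out = trial
        out.link_prob.pop(e.offspring, None)
        altered += 1
    ok, why = is_legal(out)
    assert ok, why
    return out, {"altered": altered, "confirmed": confirmed}


# ---------------------------------------------------------------------------
# End-to-end
# ---------------------------------------------------------------------------


@dataclass
class ProtocolResult:
    preliminary: Pedigree
    partial_input: Pedigree
    rates: ErrorRates
    rate_summaries: dict
    breeders: set[str]
    main_runs: list[ModalRun]
    main_pedigree: Pedigree
    report: ConsistencyReport
    final_pedigree: Pedigree
    corrections_summary: dict[str, int]


def run_protocol(
    data: StudyData,
    config: ProtocolConfig = ProtocolConfig(),
    seed: int = 0,
    ledger: CorrectionsLedger | None = None,
    territories: Mapping[str, tuple[object, int]] | None = None,
) -> ProtocolResult:
    """Run steps 1-6 and apply any documented corrections."""
    preliminary, partial, _post = step1_preliminary(data, config, seed)
    rates, summaries = step2_error_rates(data, partial, config, seed + 1000)
    breeders, _ = step3_possible_breeders(data, rates, config, seed + 2000)
    if not breeders:
        breeders = set(data.individuals)
    runs = step4_main_fit(data, rates, breeders, config, seed + 3000)
    main = step5_average(runs, config)
    report = step6_consistency(
        main, config, detection_dates=data.detection_dates,
        cohorts=data.cohorts, territories=territories,
    )
    final, summary = apply_corrections(main, ledger or CorrectionsLedger())
    return ProtocolResult(
        preliminary=preliminary,
        partial_input=partial,
        rates=rates,
        rate_summaries=summaries,
        breeders=breeders,
        main_runs=runs,
        main_pedigree=main,
        report=report,
        final_pedigree=final,
        corrections_summary=summary,
    )
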