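"""Bayesian pedigree sampler.

Estimates, for every genotyped individual, the posterior distribution
over its (dam, sire) pair — each slot being a sampled candidate or the
UNSAMPLED category — together with the sizes of the unsampled male and
female populations, under the two-stage genotyping-error model.

Sampler design
--------------
Parent pairs are updated by Gibbs sweeps: for each offspring the full
conditional over all enumerated legal (dam, sire) pairs is computed as

    likelihood(offspring | dam, sire) x w(dam) x w(sire)

where the categorical prior weight of a specific sampled candidate is
1 / (n_sampled + N_unsampled) and of the UNSAMPLED category
N_unsampled / (n_sampled + N_unsampled), N drawn from a broad lognormal
prior and updated by random-walk Metropolis-Hastings (step size tuned
during burn-in to a 30-50% acceptance window).  Pairs that would make
the offspring its own ancestor are excluded from the conditional, so
the pedigree is legal at every iteration.  Offspring are visited in
reverse detection-date order, making later-observed individuals more
likely to be fitted as offspring.

The per-pair likelihood is P(offspring observed genotype | parents'
observed genotypes): parental true genotypes are integrated over their
posterior given the observation (Hardy-Weinberg prior x error model),
the offspring's true genotype over Mendelian segregation, and the
offspring's observation over the error model.  An UNSAMPLED or
missing-at-locus parent reduces to plain Hardy-Weinberg integration.
Loci are independent; loci missing in the offspring contribute 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import beta as beta_dist

from .error_model import ErrorRates, LocusStateSpace
from .genodata import AlleleFrequencyTable
from .pedigree_core import UNSAMPLED, CohortInfo, Pedigree, is_legal

__all__ = [
    "Priors",
    "MCMCSettings",
    "PosteriorPedigree",
    "mendelian_transmission",
    "parent_pair_likelihood",
    "exclusion_filter",
    "build_candidates",
    "sample_pedigree",
    "sample_error_rates",
    "modal_pedigree",
]

Multilocus = Mapping[str, "tuple[str, str] | None"]


@dataclass(frozen=True)
class Priors:
    """Hyperpriors for the unsampled population sizes and error rates."""

    unsampled_male_mu: float = math.log(7.0)
    unsampled_male_sigma: float = 0.5
    unsampled_female_mu: float = math.log(2.0)
    unsampled_female_sigma: float = 0.5
    e1_beta: tuple[float, float] = (4.0, 100.0)
    e2_beta: tuple[float, float] = (2.0, 100.0)

    def __post_init__(self) -> None:
        vals = [
            self.unsampled_male_sigma,
            self.unsampled_female_sigma,
            *self.e1_beta,
            *self.e2_beta,
        ]
        if any(v <= 0 for v in vals):
            raise ValueError("all hyperparameters must be positive")


@dataclass
class MCMCSettings:
    iterations: int = 20000
    burn_in: int = 2000
    thinning: int = 2
    seed: int = 0
    max_mismatch_loci: int = 4
    target_acceptance: tuple[float, float] = (0.30, 0.50)
    update_unsampled_sizes: bool = True
    init_unsampled_male: float = 7.0
    init_unsampled_female: float = 2.0

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be < iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


# ---------------------------------------------------------------------------
# Likelihood kernels
# ---------------------------------------------------------------------------


def mendelian_transmission(
    offspring: tuple[str, str],
    dam: "tuple[str, str] | None",
    sire: "tuple[str, str] | None",
    locus: str,
    freqs: AlleleFrequencyTable,
) -> float:
    """P(offspring genotype | parent genotypes) under Mendelian segregation.

    A None parent is UNSAMPLED: its transmitted allele is drawn from the
    population allele frequencies (Hardy-Weinberg).
    """
    space = LocusStateSpace(locus, freqs.locus_freqs(locus))

    def _tvec(g: "tuple[str, str] | None") -> np.ndarray:
        if g is None:
            return space.p
        v = np.zeros(space.k)
        for a in g:
            v[space.alleles.index(a)] += 0.5
        return v

    td, ts = _tvec(dam), _tvec(sire)
    i = space.alleles.index(offspring[0])
    j = space.alleles.index(offspring[1])
    if i == j:
        return float(td[i] * ts[i])
    return float(td[i] * ts[j] + td[j] * ts[i])


class _LocusTables:
    """Per-locus model matrices shared by the sampler."""

    def __init__(
        self,
        locus: str,
        freqs: AlleleFrequencyTable,
        rates: ErrorRates,
        source_classes: Sequence[str],
        miscall_weighting: str = "frequency",
    ):
        self.space = LocusStateSpace(locus, freqs.locus_freqs(locus))
        self.T = self.space.transmission_tensor()  # (g, g, g)
        self.O: dict[str, np.ndarray] = {}
        self.Q: dict[str, np.ndarray] = {}
        for sc in source_classes:
            e1, e2 = rates.get(locus, sc)
            o = self.space.observation_matrix(e1, e2, miscall_weighting)
            q = o * self.space.hw[None, :]
            q /= q.sum(axis=1, keepdims=True)
            self.O[sc] = o
            self.Q[sc] = q

    def obs_row(self, state: "int | None", source_class: str) -> np.ndarray:
        """P(observed | true) over true states; ones when unobserved."""
        if state is None:
            return np.ones(self.space.n_states)
        return self.O[source_class][state]

    def post_row(self, state: "int | None", source_class: str) -> np.ndarray:
        """Posterior over a parent's true state given its observation;
        the Hardy-Weinberg prior when unobserved/unsampled."""
        if state is None:
            return self.space.hw
        return self.Q[source_class][state]


class TrioCalculator:
    """Vectorised parent-pair likelihoods over a fixed individual set."""

    def __init__(
        self,
        genotypes: Mapping[str, Multilocus],
        freqs: AlleleFrequencyTable,
        rates: ErrorRates,
        source_class: Mapping[str, str] | None = None,
        miscall_weighting: str = "frequency",
    ):
        self.ids = sorted(genotypes)
        self.freqs = freqs
        self.source_class = {
            i: (source_class or {}).get(i, "SCAT") for i in self.ids
        }
        classes = sorted(set(self.source_class.values()) | {"SCAT"})
        self.loci = freqs.loci
        self.tables = {
            loc: _LocusTables(loc, freqs, rates, classes, miscall_weighting)
            for loc in self.loci
        }
        # observed state index per (individual, locus); None = missing
        self.state: dict[str, dict[str, "int | None"]] = {}
        for i in self.ids:
            g = genotypes[i]
            st: dict[str, "int | None"] = {}
            for loc in self.loci:
                gl = g.get(loc)
                st[loc] = None if gl is None else self.tables[loc].space.state_of(gl)
            self.state[i] = st
        # parental posterior rows for every individual at every locus
        self._post: dict[str, np.ndarray] = {}
        for loc in self.loci:
            t = self.tables[loc]
            rows = [t.post_row(self.state[i][loc], self.source_class[i]) for i in self.ids]
            self._post[loc] = (
                np.stack(rows) if rows else np.zeros((0, t.space.n_states))
            )
        self._idx = {i: k for k, i in enumerate(self.ids)}

    def pair_loglik_matrix(
        self, offspring: str, dams: Sequence[str], sires: Sequence[str]
    ) -> np.ndarray:
        """Log-likelihood over (dams + UNSAMPLED) x (sires + UNSAMPLED).

        Row/column order follows the candidate lists, with the UNSAMPLED
        category appended last on each axis.
        """
        nd, ns = len(dams), len(sires)
        out = np.zeros((nd + 1, ns + 1))
        for loc in self.loci:
            t = self.tables[loc]
            o_state = self.state[offspring][loc]
            if o_state is None:
                continue  # missing offspring locus contributes 1
            ovec = t.obs_row(o_state, self.source_class[offspring])
            m = t.T @ ovec  # (g, g): dam state x sire state
            dq = np.vstack(
                [self._post[loc][[self._idx[d] for d in dams]], t.space.hw[None, :]]
                if nd
                else [t.space.hw[None, :]]
            )
            sq = np.vstack(
                [self._post[loc][[self._idx[s] for s in sires]], t.space.hw[None, :]]
                if ns
                else [t.space.hw[None, :]]
            )
            lik = dq @ m @ sq.T
            with np.errstate(divide="ignore"):
                out += np.log(lik)
        return out


def parent_pair_likelihood(
    offspring_obs: Multilocus,
    dam_obs: "Multilocus | None",
    sire_obs: "Multilocus | None",
    freqs: AlleleFrequencyTable,
    rates: ErrorRates,
    source_class: str = "SCAT",
    miscall_weighting: str = "frequency",
) -> float:
    """Log-likelihood of one parent-pair assignment (None = UNSAMPLED)."""
    genotypes: dict[str, Multilocus] = {"__off__": offspring_obs}
    dams: list[str] = []
    sires: list[str] = []
    if dam_obs is not None:
        genotypes["__dam__"] = dam_obs
        dams = ["__dam__"]
    if sire_obs is not None:
        genotypes["__sire__"] = sire_obs
        sires = ["__sire__"]
    calc = TrioCalculator(
        genotypes,
        freqs,
        rates,
        {i: source_class for i in genotypes},
        miscall_weighting,
    )
    mat = calc.pair_loglik_matrix("__off__", dams, sires)
    return float(mat[0 if dams else -1, 0 if sires else -1])


# ---------------------------------------------------------------------------
# Candidate enumeration
# ---------------------------------------------------------------------------


def _opposing_loci(g1: Multilocus, g2: Multilocus) -> int:
    n = 0
    for loc, a in g1.items():
        b = g2.get(loc)
        if a is None or b is None:
            continue
        if not (set(a) & set(b)):
            n += 1
    return n


def exclusion_filter(
    offspring_geno: Multilocus,
    candidate_geno: Multilocus,
    max_mismatch_loci: int = 4,
    offspring_birth: "int | None" = None,
    candidate_birth: "int | None" = None,
    candidate_death: "int | None" = None,
    candidate_dead_young: bool = False,
    min_breeding_age: int = 2,
) -> bool:
    """True when the candidate remains a potential parent.

    A candidate is excluded when it shares no allele with the offspring
    at more than ``max_mismatch_loci`` loci, is known to have died below
    the minimum breeding age, or — when cohorts are known — is too young
    or already dead at the offspring's conception.
    """
    if candidate_dead_young:
        return False
    if _opposing_loci(offspring_geno, candidate_geno) > max_mismatch_loci:
        return False
    if offspring_birth is not None and candidate_birth is not None:
        if candidate_birth + min_breeding_age > offspring_birth:
            return False
    if offspring_birth is not None and candidate_death is not None:
        if candidate_death < offspring_birth:
            return False
    return True


def build_candidates(
    genotypes: Mapping[str, Multilocus],
    sexes: Mapping[str, str],
    max_mismatch_loci: int = 4,
    cohorts: "CohortInfo | None" = None,
    allowed: "Sequence[str] | None" = None,
) -> dict[str, tuple[list[str], list[str]]]:
    """Per-offspring (dam candidates, sire candidates) after exclusion.

    Dams are female-or-unknown-sex, sires male-or-unknown-sex; the
    UNSAMPLED category is always available and is not listed here.
    ``allowed`` restricts candidates to a subset (possible breeders).
    """
    ids = sorted(genotypes)
    pool = set(allowed) if allowed is not None else set(ids)
    out: dict[str, tuple[list[str], list[str]]] = {}
    for o in ids:
        ob = cohorts.birth_year.get(o) if cohorts else None
        dams, sires = [], []
        for c in ids:
            if c == o or c not in pool:
                continue
            keep = exclusion_filter(
                genotypes[o],
                genotypes[c],
                max_mismatch_loci,
                offspring_birth=ob,
                candidate_birth=cohorts.birth_year.get(c) if cohorts else None,
                candidate_death=cohorts.death_year.get(c) if cohorts else None,
                candidate_dead_young=cohorts.excluded_as_parent(c) if cohorts else False,
            )
            if not keep:
                continue
            sex = sexes.get(c, "UNKNOWN")
            if sex in ("F", "UNKNOWN"):
                dams.append(c)
            if sex in ("M", "UNKNOWN"):
                sires.append(c)
        out[o] = (dams, sires)
    return out


# ---------------------------------------------------------------------------
# The sampler
# ---------------------------------------------------------------------------


@dataclass
class PosteriorPedigree:
    """Thinned posterior over parent-pair assignments.

    ``pair_counts[o]`` maps (dam, sire) — ids or the UNSAMPLED token —
    to the number of thinned samples in which the pair was assigned.
    """

    offspring: list[str]
    pair_counts: dict[str, dict[tuple[str, str], int]]
    n_samples: int
    unsampled_male: np.ndarray
    unsampled_female: np.ndarray
    loglik: np.ndarray
    acceptance: dict[str, float] = field(default_factory=dict)
    sexes: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def pair_probabilities(self, o: str) -> dict[tuple[str, str], float]:
        c = self.pair_counts[o]
        tot = sum(c.values())
        return {k: v / tot for k, v in c.items()}

    def marginals(self, o: str) -> tuple[dict[str, float], dict[str, float]]:
        dm: dict[str, float] = {}
        sm: dict[str, float] = {}
        for (d, s), p in self.pair_probabilities(o).items():
            dm[d] = dm.get(d, 0.0) + p
            sm[s] = sm.get(s, 0.0) + p
        return dm, sm

    def modal_pair(self, o: str) -> tuple[tuple[str, str], float, bool]:
        """Most frequent pair; ties break toward UNSAMPLED then lexicographic.

        Returns (pair, posterior probability, tie flag).
        """
        probs = self.pair_probabilities(o)
        best = max(probs.values())
        tied = sorted(
            [k for k, v in probs.items() if v == best],
            key=lambda k: (-(k[0] == UNSAMPLED) - (k[1] == UNSAMPLED), k),
        )
        return tied[0], best, len(tied) > 1


def modal_pedigree(posterior: PosteriorPedigree) -> Pedigree:
    """Extract the modal pedigree, repairing to legality if required.

    Offspring are assigned their most frequent pair.  Should the modal
    pairs jointly form a cycle, offspring are re-assigned greedily in
    decreasing order of modal support, each taking its most probable
    pair that keeps the configuration acyclic (the UNSAMPLED pair is
    always available), and the result is flagged REPAIRED.
    Per-link probabilities are the marginal dam/sire supports of the
    chosen pair.
    """
    if not posterior.pair_counts:
        raise ValueError("empty posterior")
    ped = Pedigree(sexes=dict(posterior.sexes))
    tie_flag = False
    for o in posterior.offspring:
        pair, _, tie = posterior.modal_pair(o)
        tie_flag |= tie
        ped.parents[o] = pair
        dm, sm = posterior.marginals(o)
        ped.link_prob[o] = (dm.get(pair[0], 0.0), sm.get(pair[1], 0.0))
    if tie_flag:
        ped.flags.append("TIE")
    ok, _ = is_legal(ped)
    if ok:
        return ped

    # greedy repair
    order = sorted(
        posterior.offspring, key=lambda o: -posterior.modal_pair(o)[1]
    )
    repaired = Pedigree(sexes=dict(posterior.sexes))
    for o in order:
        ranked = sorted(
            posterior.pair_probabilities(o).items(),
            key=lambda kv: (-kv[1], -(kv[0][0] == UNSAMPLED) - (kv[0][1] == UNSAMPLED), kv[0]),
        )
        placed = False
        for pair, _ in ranked + [((UNSAMPLED, UNSAMPLED), 0.0)]:
            repaired.parents[o] = pair
            if is_legal(repaired)[0]:
                dm, sm = posterior.marginals(o)
                repaired.link_prob[o] = (dm.get(pair[0], 0.0), sm.get(pair[1], 0.0))
                placed = True
                break
        assert placed
    repaired.flags.extend(ped.flags)
    repaired.flags.append("REPAIRED")
    # keep the offspring ordering stable
    repaired.parents = {o: repaired.parents[o] for o in posterior.offspring}
    return repaired


def _descendants(o: str, children: Mapping[str, list[str]]) -> set[str]:
    seen: set[str] = set()
    stack = [o]
    while stack:
        x = stack.pop()
        for c in children.get(x, ()):
            if c not in seen:
                seen.add(c)
                stack.append(c)
    return seen


def sample_pedigree(
    genotypes: Mapping[str, Multilocus],
    sexes: Mapping[str, str],
    freqs: AlleleFrequencyTable,
    rates: ErrorRates,
    priors: Priors = Priors(),
    settings: MCMCSettings = MCMCSettings(),
    cohorts: "CohortInfo | None" = None,
    detection_dates: Mapping[str, object] | None = None,
    candidates: Mapping[str, tuple[list[str], list[str]]] | None = None,
    source_class: Mapping[str, str] | None = None,
) -> PosteriorPedigree:
    """Run the Gibbs/MH chain and return the thinned posterior.

    ``candidates`` overrides the default exclusion-filtered candidate
    sets (used by the protocol's breeder-restricted main fit).  With
    ``settings.update_unsampled_sizes`` False, the unsampled sizes stay
    fixed at their initial values (exact enumeration checks rely on
    this).  Runs are reproducible bit-for-bit at a fixed seed.
    """
    rng = np.random.default_rng(settings.seed)
    ids = sorted(genotypes)
    if candidates is None:
        candidates = build_candidates(
            genotypes, sexes, settings.max_mismatch_loci, cohorts
        )
    calc = TrioCalculator(genotypes, freqs, rates, source_class)

    # later-observed individuals are visited as offspring first
    if detection_dates:
        sweep = sorted(ids, key=lambda i: (detection_dates.get(i),), reverse=True)
    else:
        sweep = list(ids)

    lik_exp: dict[str, np.ndarray] = {}
    dam_lists: dict[str, list[str]] = {}
    sire_lists: dict[str, list[str]] = {}
    dam_pos: dict[str, dict[str, int]] = {}
    sire_pos: dict[str, dict[str, int]] = {}
    for o in ids:
        dams, sires = candidates[o]
        ll = calc.pair_loglik_matrix(o, dams, sires)
        finite = ll[np.isfinite(ll)]
        shift = finite.max() if finite.size else 0.0
        lik_exp[o] = np.exp(ll - shift)
        dam_lists[o], sire_lists[o] = list(dams), list(sires)
        dam_pos[o] = {d: k for k, d in enumerate(dams)}
        sire_pos[o] = {s: k for k, s in enumerate(sires)}

    # state
    assign: dict[str, tuple[str, str]] = {o: (UNSAMPLED, UNSAMPLED) for o in ids}
    children: dict[str, list[str]] = {}
    n_f = float(settings.init_unsampled_female)
    n_m = float(settings.init_unsampled_male)
    step_f = step_m = 0.5
    acc_f: list[int] = []
    acc_m: list[int] = []

    n_dam_cands = {o: len(dam_lists[o]) for o in ids}
    n_sire_cands = {o: len(sire_lists[o]) for o in ids}

    def _n_logpost(n: float, female: bool) -> float:
        if n <= 0:
            return -math.inf
        mu = priors.unsampled_female_mu if female else priors.unsampled_male_mu
        sig = priors.unsampled_female_sigma if female else priors.unsampled_male_sigma
        z = (math.log(n) - mu) / sig
        lp = -0.5 * z * z - math.log(n * sig) - 0.5 * math.log(2 * math.pi)
        for o in ids:
            d, s = assign[o]
            if female:
                lp += (math.log(n) if d == UNSAMPLED else 0.0) - math.log(
                    n_dam_cands[o] + n
                )
            else:
                lp += (math.log(n) if s == UNSAMPLED else 0.0) - math.log(
                    n_sire_cands[o] + n
                )
        return lp

    pair_counts: dict[str, dict[tuple[str, str], int]] = {o: {} for o in ids}
    rec_nm: list[float] = []
    rec_nf: list[float] = []
    rec_ll: list[float] = []

    def _set_parents(o: str, pair: tuple[str, str]) -> None:
        old = assign[o]
        for p in old:
            if p != UNSAMPLED and p in children:
                lst = children[p]
                if o in lst:
                    lst.remove(o)
        assign[o] = pair
        for p in pair:
            if p != UNSAMPLED:
                children.setdefault(p, []).append(o)

    total_ll = 0.0
    for it in range(settings.iterations):
        for o in sweep:
            w = lik_exp[o].copy()
            # prior weights: sampled candidate 1, UNSAMPLED category N
            w[-1, :] *= n_f
            w[:, -1] *= n_m
            # legality: descendants of o cannot be its parents
            desc = _descendants(o, children)
            if desc:
                dp, sp = dam_pos[o], sire_pos[o]
                for x in desc:
                    if x in dp:
                        w[dp[x], :] = 0.0
                    if x in sp:
                        w[:, sp[x]] = 0.0
            flat = w.ravel()
            tot = flat.sum()
            if tot <= 0 or not np.isfinite(tot):
                pair = (UNSAMPLED, UNSAMPLED)
            else:
                u = rng.random() * tot
                idx = int(np.searchsorted(np.cumsum(flat), u, side="right"))
                idx = min(idx, flat.size - 1)
                di, si = divmod(idx, w.shape[1])
                dam = dam_lists[o][di] if di < len(dam_lists[o]) else UNSAMPLED
                sire = sire_lists[o][si] if si < len(sire_lists[o]) else UNSAMPLED
                pair = (dam, sire)
            if pair != assign[o]:
                _set_parents(o, pair)

        if settings.update_unsampled_sizes:
            for female in (True, False):
                n0 = n_f if female else n_m
                step = step_f if female else step_m
                prop = n0 * math.exp(rng.normal(0.0, step))
                # log-scale random walk: proposal ratio = prop / n0
                logr = (
                    _n_logpost(prop, female)
                    - _n_logpost(n0, female)
                    + math.log(prop)
                    - math.log(n0)
                )
                accept = math.log(rng.random()) < logr
                if female:
                    n_f = prop if accept else n_f
                    acc_f.append(int(accept))
                else:
                    n_m = prop if accept else n_m
                    acc_m.append(int(accept))
            # tune during burn-in
            if it < settings.burn_in and (it + 1) % 50 == 0:
                lo, hi = settings.target_acceptance
                for acc, which in ((acc_f, "f"), (acc_m, "m")):
                    rate = float(np.mean(acc[-50:]))
                    factor = 1.0
                    if rate < lo:
                        factor = 1 / 1.25
                    elif rate > hi:
                        factor = 1.25
                    if which == "f":
                        step_f *= factor
                    else:
                        step_m *= factor

        if it >= settings.burn_in and (it - settings.burn_in) % settings.thinning == 0:
            total_ll = 0.0
            for o in ids:
                d, s = assign[o]
                di = dam_pos[o].get(d, len(dam_lists[o]))
                si = sire_pos[o].get(s, len(sire_lists[o]))
                with np.errstate(divide="ignore"):
                    total_ll += float(np.log(lik_exp[o][di, si]))
                pc = pair_counts[o]
                pc[(d, s)] = pc.get((d, s), 0) + 1
            rec_nm.append(n_m)
            rec_nf.append(n_f)
            rec_ll.append(total_ll)

    post = PosteriorPedigree(
        offspring=ids,
        pair_counts=pair_counts,
        n_samples=len(rec_ll),
        unsampled_male=np.array(rec_nm),
        unsampled_female=np.array(rec_nf),
        loglik=np.array(rec_ll),
        sexes=dict(sexes),
    )
    if settings.update_unsampled_sizes:
        lo, hi = settings.target_acceptance
        post_burn = max(len(acc_f) - (settings.iterations - settings.burn_in), 0)
        for acc, name in ((acc_f, "unsampled_female"), (acc_m, "unsampled_male")):
            rate = float(np.mean(acc[post_burn:])) if acc[post_burn:] else math.nan
            post.acceptance[name] = rate
            if not (lo <= rate <= hi):
                post.warnings.append(
                    f"{name} acceptance {rate:.2f} outside [{lo:.2f}, {hi:.2f}]"
                )
    return post


# ---------------------------------------------------------------------------
# Error-rate estimation (protocol step 2: pedigree fixed)
# ---------------------------------------------------------------------------


def _mendelian_prior(
    tables: _LocusTables,
    dam_state: "int | None",
    sire_state: "int | None",
    source_class: str,
) -> np.ndarray:
    """Prior over an offspring's true state given fixed parents.

    Parents' consensus genotypes are taken as their true genotypes;
    a missing/unsampled parent is integrated over Hardy-Weinberg.
    """
    space = tables.space
    if dam_state is None and sire_state is None:
        return space.hw
    t = tables.T

    def _onehot(state: "int | None") -> np.ndarray:
        if state is None:
            return space.hw
        v = np.zeros(space.n_states)
        v[state] = 1.0
        return v

    return np.einsum("d,s,dso->o", _onehot(dam_state), _onehot(sire_state), t)


def sample_error_rates(
    replicate_states: Mapping[str, Mapping[str, Sequence["tuple[str, str] | None"]]],
    freqs: AlleleFrequencyTable,
    fixed_pedigree: "Pedigree | None" = None,
    individual_genotypes: Mapping[str, Multilocus] | None = None,
    sample_to_individual: Mapping[str, str] | None = None,
    priors: Priors = Priors(),
    iterations: int = 3000,
    burn_in: int = 500,
    init: float = 0.1,
    seed: int = 0,
    source_class: str = "SCAT",
    miscall_weighting: str = "frequency",
) -> tuple[ErrorRates, "dict[str, dict[str, tuple[float, float, float]]]"]:
    """Per-locus posterior for (E1, E2) with the pedigree kept fixed.

    ``replicate_states`` maps sample_id -> locus -> replicate allele
    pairs.  All replicates of all samples of an individual share one
    latent true genotype, whose prior is Hardy-Weinberg — or, when the
    fixed pedigree assigns the individual sampled parents, Mendelian
    transmission from the parents' consensus genotypes.  E1 and E2 are
    updated jointly by random-walk Metropolis-Hastings on the logit
    scale under their Beta priors, initialised at ``init``.

    Returns (ErrorRates holding the per-locus posterior means, and a
    per-locus summary {"E1"|"E2": (mean, ci_lo, ci_hi)}).  Loci with no
    informative replicates fall back to the prior and are flagged by a
    mean equal to the prior mean.
    """
    rng = np.random.default_rng(seed)
    sample_to_individual = sample_to_individual or {
        s: s for s in replicate_states
    }
    a1, b1 = priors.e1_beta
    a2, b2 = priors.e2_beta

    # group replicate observations by individual
    by_ind: dict[str, dict[str, list["tuple[str, str] | None"]]] = {}
    for sid, by_locus in replicate_states.items():
        ind = sample_to_individual.get(sid, sid)
        d = by_ind.setdefault(ind, {})
        for loc, reps in by_locus.items():
            d.setdefault(loc, []).extend(reps)

    summaries: dict[str, dict[str, tuple[float, float, float]]] = {}
    rates_out = ErrorRates()
    dummy_rates = ErrorRates(init, init)

    for loc in freqs.loci:
        tables = _LocusTables(loc, freqs, dummy_rates, [source_class], miscall_weighting)
        space = tables.space
        g = space.n_states
        counts: list[np.ndarray] = []
        priors_true: list[np.ndarray] = []
        for ind, by_locus in sorted(by_ind.items()):
            reps = [r for r in by_locus.get(loc, []) if r is not None]
            if not reps:
                continue
            n = np.zeros(g)
            for r in reps:
                n[space.state_of(r)] += 1
            counts.append(n)
            prior = space.hw
            if fixed_pedigree is not None and ind in fixed_pedigree.parents:
                d, s = fixed_pedigree.parents[ind]

                def _pstate(p: str) -> "int | None":
                    if individual_genotypes is None or p in (UNSAMPLED, "UNKNOWN"):
                        return None
                    gp = individual_genotypes.get(p, {}).get(loc)
                    return None if gp is None else space.state_of(gp)

                prior = _mendelian_prior(tables, _pstate(d), _pstate(s), source_class)
            priors_true.append(prior)
        if not counts:
            m1 = a1 / (a1 + b1)
            m2 = a2 / (a2 + b2)
            summaries[loc] = {
                "E1": (m1, float(beta_dist.ppf(0.025, a1, b1)), float(beta_dist.ppf(0.975, a1, b1))),
                "E2": (m2, float(beta_dist.ppf(0.025, a2, b2)), float(beta_dist.ppf(0.975, a2, b2))),
                "prior_only": (1.0, 1.0, 1.0),
            }
            rates_out.set(loc, source_class, m1, m2)
            continue
        nmat = np.stack(counts)  # (n_ind, g_obs)
        log_prior_true = np.log(np.stack(priors_true) + 1e-300)

        def _loglik(e1: float, e2: float) -> float:
            o = space.observation_matrix(e1, e2, miscall_weighting)
            logo = np.log(o + 1e-300)
            per_true = nmat @ logo + log_prior_true  # (n_ind, g_true)
            m = per_true.max(axis=1, keepdims=True)
            return float(np.sum(m[:, 0] + np.log(np.exp(per_true - m).sum(axis=1))))

        def _logpost(e1: float, e2: float) -> float:
            lp = float(
                beta_dist.logpdf(e1, a1, b1) + beta_dist.logpdf(e2, a2, b2)
            )
            return lp + _loglik(e1, e2)

        def _logit(x: float) -> float:
            return math.log(x / (1 - x))

        def _expit(x: float) -> float:
            return 1 / (1 + math.exp(-x))

        z1, z2 = _logit(init), _logit(init)
        lp = _logpost(init, init) + math.log(init * (1 - init)) * 2
        step = 0.4
        chain = np.empty((iterations, 2))
        acc: list[int] = []
        for it in range(iterations):
            z1p = z1 + rng.normal(0, step)
            z2p = z2 + rng.normal(0, step)
            e1p, e2p = _expit(z1p), _expit(z2p)
            # include the logit-transform Jacobian
            lpp = _logpost(e1p, e2p) + math.log(e1p * (1 - e1p)) + math.log(
                e2p * (1 - e2p)
            )
            if math.log(rng.random()) < lpp - lp:
                z1, z2, lp = z1p, z2p, lpp
                acc.append(1)
            else:
                acc.append(0)
            if it < burn_in and (it + 1) % 50 == 0:
                rate = float(np.mean(acc[-50:]))
                if rate < 0.2:
                    step /= 1.3
                elif rate > 0.5:
                    step *= 1.3
            chain[it] = (_expit(z1), _expit(z2))
        kept = chain[burn_in:]
        summaries[loc] = {
            "E1": (
                float(kept[:, 0].mean()),
                float(np.quantile(kept[:, 0], 0.025)),
                float(np.quantile(kept[:, 0], 0.975)),
            ),
            "E2": (
                float(kept[:, 1].mean()),
                float(np.quantile(kept[:, 1], 0.025)),
                float(np.quantile(kept[:, 1], 0.975)),
            ),
        }
        rates_out.set(
            loc, source_class, float(kept[:, 0].mean()), float(kept[:, 1].mean())
        )
    return rates_out, summaries
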