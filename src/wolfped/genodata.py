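"""Core genotype data structures and individual identification.

Loci, allele-frequency tables, replicate PCR observations, consensus
genotype calling from triplicate amplifications, multilocus genotype
matching, sample-to-individual clustering, and allele-frequency based
diversity/inbreeding statistics for non-invasive microsatellite data.

Genotypes are unordered allele pairs.  Throughout the package a genotype
is a 2-tuple of allele labels sorted lexicographically, or ``None`` for
missing data.  Allele labels are opaque strings: no stepwise-mutation
ordering is assumed.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "Genotype",
    "Locus",
    "AlleleFrequencyTable",
    "ReplicateObservation",
    "ConsensusStatus",
    "ConsensusGenotype",
    "ConsensusRules",
    "SampleRecord",
    "IndividualRecord",
    "MatchRule",
    "MatchResult",
    "as_genotype",
    "call_consensus",
    "match_genotypes",
    "cluster_samples",
    "expected_heterozygosity",
    "augment_frequencies",
    "allele_frequency_inbreeding",
]

#: Unordered allele pair (sorted) or None for missing.
Genotype = "tuple[str, str] | None"


def as_genotype(a: str | None, b: str | None) -> tuple[str, str] | None:
    """Normalise two allele calls into a sorted unordered pair (or None)."""
    if a is None or b is None or a == "" or b == "":
        return None
    a, b = str(a), str(b)
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class Locus:
    """A microsatellite locus and its known allele labels."""

    id: str
    alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.alleles) < 1:
            raise ValueError(f"locus {self.id}: needs at least one allele")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"locus {self.id}: duplicate allele labels")


class AlleleFrequencyTable:
    """Per-locus allele frequencies (reference population).

    Frequencies must be positive and sum to 1 per locus within 1e-9.
    """

    def __init__(self, freqs: Mapping[str, Mapping[str, float]]):
        self._freqs: dict[str, dict[str, float]] = {
            loc: dict(d) for loc, d in freqs.items()
        }
        self.validate()

    def validate(self) -> None:
        if not self._freqs:
            raise ValueError("empty allele-frequency table")
        for loc, d in self._freqs.items():
            if not d:
                raise ValueError(f"locus {loc}: no alleles")
            if any(p <= 0 for p in d.values()):
                raise ValueError(f"locus {loc}: non-positive frequency")
            s = sum(d.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"locus {loc}: frequencies sum to {s!r}, not 1")

    @property
    def loci(self) -> list[str]:
        return list(self._freqs)

    def alleles(self, locus: str) -> list[str]:
        return sorted(self._freqs[locus])

    def freq(self, locus: str, allele: str) -> float:
        return self._freqs[locus][allele]

    def locus_freqs(self, locus: str) -> dict[str, float]:
        return dict(self._freqs[locus])

    def locus_object(self, locus: str) -> Locus:
        return Locus(locus, tuple(self.alleles(locus)))

    def __contains__(self, locus: str) -> bool:
        return locus in self._freqs

    def __eq__(self, other: object) -> bool:
        return isinstance(other, AlleleFrequencyTable) and self._freqs == other._freqs

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"locus": loc, "allele": a, "frequency": p}
            for loc, d in self._freqs.items()
            for a, p in sorted(d.items())
        ]
        return pd.DataFrame(rows, columns=["locus", "allele", "frequency"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AlleleFrequencyTable":
        freqs: dict[str, dict[str, float]] = {}
        for row in df.itertuples(index=False):
            freqs.setdefault(str(row.locus), {})[str(row.allele)] = float(row.frequency)
        return cls(freqs)


@dataclass(frozen=True)
class ReplicateObservation:
    """One replicate PCR allele call for a sample at a locus."""

    sample_id: str
    locus_id: str
    replicate_index: int  # 1-based
    allele_pair: tuple[str, str] | None  # sorted pair, or None = no amplification

    def __post_init__(self) -> None:
        if self.replicate_index < 1:
            raise ValueError("replicate_index must be >= 1")


class ConsensusStatus(str, enum.Enum):
    RELIABLE_HET = "RELIABLE_HET"
    RELIABLE_HOM = "RELIABLE_HOM"
    UNRESOLVED = "UNRESOLVED"
    MISSING = "MISSING"


@dataclass(frozen=True)
class ConsensusGenotype:
    sample_id: str
    locus_id: str
    genotype: tuple[str, str] | None
    status: ConsensusStatus
    replicates_used: int

    def __post_init__(self) -> None:
        if self.status is ConsensusStatus.RELIABLE_HET:
            assert self.genotype is not None and self.genotype[0] != self.genotype[1]
        elif self.status is ConsensusStatus.RELIABLE_HOM:
            assert self.genotype is not None and self.genotype[0] == self.genotype[1]
        else:
            assert self.genotype is None


@dataclass(frozen=True)
class ConsensusRules:
    """Reliability rules for replicate PCR genotypes.

    A heterozygote is reliable when both alleles are each seen in at
    least ``het_min_replicates`` replicates of the evaluated triplicate;
    a homozygote when every replicate of the triplicate shows the same
    homozygous call.  With ``pooled=False`` (the sequential lab
    workflow) the second triplicate is evaluated on its own; with
    ``pooled=True`` all available replicates are evaluated together.
    """

    het_min_replicates: int = 2
    triplicate_size: int = 3
    max_replicates: int = 6
    pooled: bool = False


def _eval_triplicate(
    pairs: Sequence[tuple[str, str] | None],
    rules: ConsensusRules,
    pooled_size: int | None = None,
) -> tuple[str, str] | None:
    """Apply the reliability rule to one batch of replicate calls.

    Returns the reliable genotype or None if the batch is unresolved.
    """
    informative = [p for p in pairs if p is not None]
    # Heterozygote: both alleles of the pair observed together in
    # >= het_min_replicates replicates of the batch.  Counting alleles
    # separately would accept the conflicting pattern {AA, AB, BB},
    # where two replicates show opposing homozygotes.
    counts: dict[tuple[str, str], int] = {}
    for p in informative:
        counts[p] = counts.get(p, 0) + 1
    het_supported = sorted(
        g for g, n in counts.items() if g[0] != g[1] and n >= rules.het_min_replicates
    )
    if len(het_supported) == 1:
        return het_supported[0]
    if len(het_supported) > 1:
        return None  # two conflicting supported heterozygotes (pooled mode)
    # Homozygote: identical homozygous call in *all* replicates of the
    # full triplicate (a missing replicate therefore blocks the call).
    need = pooled_size if pooled_size is not None else rules.triplicate_size
    if len(pairs) >= need and len(informative) == len(pairs):
        homs = {p for p in informative}
        if len(homs) == 1:
            (g,) = homs
            if g[0] == g[1]:
                return g
    return None


def call_consensus(
    replicates: Sequence[ReplicateObservation],
    rules: ConsensusRules = ConsensusRules(),
) -> ConsensusGenotype:
    """Derive the consensus genotype of one sample at one locus.

    Replicates 1-3 form the first triplicate.  If it yields no reliable
    call and no further replicates are available the result is
    UNRESOLVED (a second triplicate is requested); with replicates 4-6
    present the second triplicate is evaluated (on its own by default,
    pooled with the first if ``rules.pooled``); if neither batch
    resolves, the locus is MISSING.
    """
    if not 1 <= len(replicates) <= rules.max_replicates:
        raise ValueError(f"expected 1-{rules.max_replicates} replicates, got {len(replicates)}")
    sids = {r.sample_id for r in replicates}
    lids = {r.locus_id for r in replicates}
    if len(sids) != 1 or len(lids) != 1:
        raise ValueError(f"mixed sample/locus ids: samples={sorted(sids)} loci={sorted(lids)}")
    sample_id, locus_id = replicates[0].sample_id, replicates[0].locus_id

    ordered = sorted(replicates, key=lambda r: r.replicate_index)
    pairs = [r.allele_pair for r in ordered]
    first = pairs[: rules.triplicate_size]
    second = pairs[rules.triplicate_size :]

    def _result(g: tuple[str, str] | None, status: ConsensusStatus) -> ConsensusGenotype:
        return ConsensusGenotype(sample_id, locus_id, g, status, len(replicates))

    g = _eval_triplicate(first, rules)
    if g is None and second:
        if rules.pooled:
            g = _eval_triplicate(pairs, rules, pooled_size=len(pairs))
        else:
            g = _eval_triplicate(second, rules)
    if g is not None:
        status = (
            ConsensusStatus.RELIABLE_HET if g[0] != g[1] else ConsensusStatus.RELIABLE_HOM
        )
        return _result(g, status)
    if len(replicates) <= rules.triplicate_size:
        return _result(None, ConsensusStatus.UNRESOLVED)
    return _result(None, ConsensusStatus.MISSING)


@dataclass(frozen=True)
class SampleRecord:
    """Field metadata for one collected sample."""

    sample_id: str
    date: date
    x: float
    y: float
    source_class: str = "SCAT"  # SCAT | TISSUE_SECRETION
    collector: str = ""
    species_flag: str = "WOLF"  # WOLF | NON_WOLF | UNKNOWN

    def __post_init__(self) -> None:
        if self.source_class not in ("SCAT", "TISSUE_SECRETION"):
            raise ValueError(f"bad source_class {self.source_class!r}")
        if self.species_flag not in ("WOLF", "NON_WOLF", "UNKNOWN"):
            raise ValueError(f"bad species_flag {self.species_flag!r}")


@dataclass
class IndividualRecord:
    """A clustered individual with its consensus multilocus genotype."""

    individual_id: str
    genotype: dict[str, tuple[str, str] | None]
    sex: str = "UNKNOWN"  # M | F | UNKNOWN
    sample_ids: list[str] = field(default_factory=list)
    first_seen: date | None = None
    last_seen: date | None = None
    death_date: date | None = None
    known_age_at_death: int | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def n_loci_typed(self) -> int:
        return sum(1 for g in self.genotype.values() if g is not None)


# ---------------------------------------------------------------------------
# Genotype matching and clustering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MatchRule:
    """Multilocus match rule for assigning samples to individuals.

    Two genotypes are the same individual when they disagree at no more
    than ``max_mismatch_alleles`` alleles overall, with (by default) at
    most one mismatching allele per locus — two genotyping errors at
    one locus would produce a genotype unrelated to the true one, so a
    concentrated double mismatch is treated as a true difference.
    Comparisons with fewer than ``min_overlap`` shared typed loci are
    NO_CALL.
    """

    max_mismatch_alleles: int = 2
    one_per_locus: bool = True
    min_overlap: int = 8


@dataclass(frozen=True)
class MatchResult:
    is_match: bool
    mismatching_alleles: int
    loci_compared: int
    no_call: bool = False


def _locus_mismatch(g1: tuple[str, str], g2: tuple[str, str]) -> int:
    """Allele mismatches at one locus: 2 - |maximal multiset intersection|."""
    a = list(g1)
    shared = 0
    for x in g2:
        if x in a:
            a.remove(x)
            shared += 1
    return 2 - shared


def match_genotypes(
    g1: Mapping[str, tuple[str, str] | None],
    g2: Mapping[str, tuple[str, str] | None],
    rule: MatchRule = MatchRule(),
) -> MatchResult:
    """Compare two multilocus genotypes under the mismatch-tolerance rule."""
    shared = [
        loc
        for loc in g1
        if loc in g2 and g1[loc] is not None and g2[loc] is not None
    ]
    if len(shared) < rule.min_overlap:
        return MatchResult(False, 0, len(shared), no_call=True)
    total = 0
    concentrated = False
    for loc in shared:
        m = _locus_mismatch(g1[loc], g2[loc])  # type: ignore[arg-type]
        total += m
        if m >= 2:
            concentrated = True
    ok = total <= rule.max_mismatch_alleles
    if rule.one_per_locus and concentrated:
        ok = False
    return MatchResult(ok, total, len(shared))


def _majority_consensus(
    genos: Sequence[Mapping[str, tuple[str, str] | None]], loci: Sequence[str]
) -> dict[str, tuple[str, str] | None]:
    out: dict[str, tuple[str, str] | None] = {}
    for loc in loci:
        calls = [g[loc] for g in genos if g.get(loc) is not None]
        if not calls:
            out[loc] = None
            continue
        counts: dict[tuple[str, str], int] = {}
        for c in calls:
            counts[c] = counts.get(c, 0) + 1  # type: ignore[index]
        best = max(counts.items(), key=lambda kv: (kv[1], kv[0]))  # ties: lexicographic
        out[loc] = best[0]
    return out


def cluster_samples(
    sample_genotypes: Mapping[str, Mapping[str, tuple[str, str] | None]],
    rule: MatchRule = MatchRule(),
    sample_meta: Mapping[str, SampleRecord] | None = None,
    min_loci_consensus: int = 11,
    id_prefix: str = "IND",
) -> tuple[list[IndividualRecord], list[str]]:
    """Cluster samples into individuals by pairwise genotype matching.

    Builds the match graph over samples, takes connected components as
    individuals, and derives each individual's consensus genotype by
    per-locus majority over its member samples.  Components containing
    an internal pairwise *mismatch* (not NO_CALL) are flagged AMBIGUOUS
    but kept together.  Individuals whose consensus is typed at fewer
    than ``min_loci_consensus`` loci are returned in the rejected list.

    Returns (individuals, rejected_sample_ids).
    """
    import networkx as nx

    ids = sorted(sample_genotypes)
    loci = sorted({loc for g in sample_genotypes.values() for loc in g})
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    mismatched_pairs: set[tuple[str, str]] = set()
    for i, s1 in enumerate(ids):
        for s2 in ids[i + 1 :]:
            res = match_genotypes(sample_genotypes[s1], sample_genotypes[s2], rule)
            if res.is_match:
                graph.add_edge(s1, s2)
            elif not res.no_call:
                mismatched_pairs.add((s1, s2))

    individuals: list[IndividualRecord] = []
    rejected: list[str] = []
    comps = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    k = 0
    for comp in comps:
        members = sorted(comp)
        consensus = _majority_consensus([sample_genotypes[s] for s in members], loci)
        n_typed = sum(1 for g in consensus.values() if g is not None)
        if n_typed < min_loci_consensus:
            rejected.extend(members)
            continue
        k += 1
        flags = []
        if any(
            (a, b) in mismatched_pairs
            for i, a in enumerate(members)
            for b in members[i + 1 :]
        ):
            flags.append("AMBIGUOUS")
        rec = IndividualRecord(
            individual_id=f"{id_prefix}-{k:03d}",
            genotype=consensus,
            sample_ids=members,
            flags=flags,
        )
        if sample_meta:
            dates = sorted(sample_meta[s].date for s in members if s in sample_meta)
            if dates:
                rec.first_seen, rec.last_seen = dates[0], dates[-1]
        individuals.append(rec)
    return individuals, rejected


# ---------------------------------------------------------------------------
# Frequency-based statistics
# ---------------------------------------------------------------------------


def expected_heterozygosity(
    freqs: AlleleFrequencyTable, unbiased_n: int | None = None
) -> tuple[pd.Series, float, float]:
    """Nei gene diversity per locus and the panel mean +/- se.

    H_E = 1 - sum_a p_a^2 per locus.  If ``unbiased_n`` is given the
    small-sample correction n/(n-1) is applied.  Returns
    (per-locus Series, panel mean, standard error over loci).
    """
    he = {}
    for loc in freqs.loci:
        p = np.array(list(freqs.locus_freqs(loc).values()))
        h = 1.0 - float(np.sum(p**2))
        if unbiased_n is not None:
            h *= unbiased_n / (unbiased_n - 1)
        he[loc] = h
    s = pd.Series(he).sort_index()
    mean = float(s.mean())
    se = float(s.std(ddof=1) / math.sqrt(len(s))) if len(s) > 1 else 0.0
    return s, mean, se


def augment_frequencies(
    base: AlleleFrequencyTable,
    observed_alleles: Mapping[str, Iterable[str]],
    epsilon: float = 0.005,
) -> AlleleFrequencyTable:
    """Add observed-but-absent alleles at low frequency and renormalise.

    Alleles seen in the study samples but absent from the reference
    frequency table are inserted at ``epsilon`` each, then per-locus
    frequencies are rescaled to sum to 1.
    """
    if not 0 < epsilon <= 0.05:
        raise ValueError("epsilon must be in (0, 0.05]")
    out: dict[str, dict[str, float]] = {}
    for loc in base.loci:
        d = base.locus_freqs(loc)
        novel = sorted(set(observed_alleles.get(loc, ())) - set(d))
        for a in novel:
            d[a] = epsilon
        total = sum(d.values())
        out[loc] = {a: p / total for a, p in d.items()}
    return AlleleFrequencyTable(out)


def _neg_loglik_F(
    f: float,
    genos: Sequence[tuple[str, str]],
    locus_freqs: Sequence[Mapping[str, float]],
) -> float:
    ll = 0.0
    for g, pf in zip(genos, locus_freqs):
        a, b = g
        if a == b:
            p = pf[a]
            lik = p * p * (1 - f) + p * f
        else:
            lik = 2 * pf[a] * pf[b] * (1 - f)
        if lik <= 0:
            return math.inf
        ll += math.log(lik)
    return -ll


def allele_frequency_inbreeding(
    individuals: Mapping[str, Mapping[str, tuple[str, str] | None]],
    freqs: AlleleFrequencyTable,
) -> tuple[pd.Series, float, float]:
    """Per-individual maximum-likelihood inbreeding coefficient F-hat.

    Under P(hom aa | F) = p_a^2 (1-F) + p_a F and
    P(het ab | F) = 2 p_a p_b (1-F), maximise the product over typed
    loci on F in [0, 1].  Individuals with no typed locus in the
    frequency table are excluded with a warning.  Returns
    (per-individual Series, population mean, se).
    """
    fhat: dict[str, float] = {}
    for ind, geno in individuals.items():
        genos: list[tuple[str, str]] = []
        locus_freqs: list[Mapping[str, float]] = []
        for loc, g in geno.items():
            if g is None or loc not in freqs:
                continue
            pf = freqs.locus_freqs(loc)
            if g[0] not in pf or g[1] not in pf:
                continue
            genos.append(g)
            locus_freqs.append(pf)
        if not genos:
            warnings.warn(f"individual {ind}: no usable loci, excluded from F-hat")
            continue
        res = minimize_scalar(
            _neg_loglik_F,
            bounds=(0.0, 1.0),
            args=(genos, locus_freqs),
            method="bounded",
            options={"xatol": 1e-6},
        )
        # compare against the boundary values explicitly (bounded Brent
        # can sit just inside a boundary optimum)
        cands = [(float(res.x), res.fun)]
        for f0 in (0.0, 1.0):
            cands.append((f0, _neg_loglik_F(f0, genos, locus_freqs)))
        fhat[ind] = min(cands, key=lambda t: t[1])[0]
    s = pd.Series(fhat).sort_index()
    mean = float(s.mean()) if len(s) else math.nan
    se = float(s.std(ddof=1) / math.sqrt(len(s))) if len(s) > 1 else 0.0
    return s, mean, se
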