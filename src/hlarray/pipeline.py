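"""End-to-end typing: normalize → serotype → template match → genotype →
ambiguity removal → validation flagging.

A single confirmed call per locus is reported as ``allele / Nil``
(homozygous).  Every result carries flags describing why it should (or need
not) be confirmed by sequencing: homozygous calls and calls with two alleles
of the same serotype are exactly the classes in which array typing errs, so
they are always flagged for validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .catalog import AlleleCatalog, SerogroupTable
from .genotyping import (
    AMBIGUITY_MARGIN,
    Genotype,
    build_comparison_vector,
    frequency_tiebreak,
    resolve_ambiguity,
    weight_based_selection,
)
from .knowledgebase import Knowledgebase, MatchDecision
from .probes import ProbeSet
from .serotyping import (
    DEFAULT_MAX_DIFFERENCE,
    HOMOZYGOUS_MARGIN,
    LocusCall,
    locus_allele_negatives,
    serotype_locus,
)
from .signals import (
    DEFAULT_DEGRADED_RATIO,
    DEFAULT_INITIAL_FRACTION,
    ArraySignals,
    ThresholdTable,
    binarize,
    correct_errors,
    normalize_signals,
    qc_array,
)

NIL = "Nil"
NO_SIGNAL_MAX = 5000.0  # normalized scale: below this no probe is truly positive

FLAGS = frozenset(
    {"homozygous", "close-alleles", "degraded", "no-call", "ambiguous", "template-derived"}
)


@dataclass
class TypingConfig:
    homozygous_margin: float = HOMOZYGOUS_MARGIN
    max_difference: float = DEFAULT_MAX_DIFFERENCE
    ambiguity_margin: float = AMBIGUITY_MARGIN
    initial_fraction: float = DEFAULT_INITIAL_FRACTION
    degraded_ratio: float = DEFAULT_DEGRADED_RATIO
    no_signal_max: float = NO_SIGNAL_MAX
    correction_window: int = 5
    correction_factor: float = 3.0
    weight_threshold: float = 0.0
    allele_tie_margin: float = 20.0
    exclude_uninformative: bool = False


@dataclass
class TypingResult:
    """Per-sample typing call, serializable and round-trippable."""

    sample_id: str
    calls: dict[str, tuple[str, str]]  # locus -> (allele1, allele2 | Nil)
    flags: set[str] = field(default_factory=set)
    provenance: str = "knowledge-based"  # 'template' | 'knowledge-based' | 'none'
    genotypes: list[tuple[Genotype, float]] = field(default_factory=list)
    matched_template: str | None = None
    template_r: float | None = None
    log: dict = field(default_factory=dict)

    @property
    def no_call(self) -> bool:
        return "no-call" in self.flags

    def genotype(self) -> Genotype:
        """The called genotype (Nil dropped)."""
        return {
            l: tuple(a for a in pair if a != NIL and a) for l, pair in self.calls.items()
        }

    def serotype_sets(self) -> dict[str, set[str]]:
        return {
            l: {a.rsplit(":", 1)[0] for a in pair if a != NIL and a}
            for l, pair in self.calls.items()
        }

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "calls": {l: list(self.calls[l]) for l in sorted(self.calls)},
            "flags": sorted(self.flags),
            "provenance": self.provenance,
            "genotypes": [
                {"alleles": {l: list(g[l]) for l in sorted(g)}, "wins": w}
                for g, w in self.genotypes
            ],
            "matched_template": self.matched_template,
            "template_r": self.template_r,
            "log": self.log,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "TypingResult":
        return cls(
            d["sample_id"],
            {l: tuple(v) for l, v in d["calls"].items()},
            set(d["flags"]),
            d["provenance"],
            [({l: tuple(a) for l, a in g["alleles"].items()}, g["wins"]) for g in d["genotypes"]],
            d.get("matched_template"),
            d.get("template_r"),
            d.get("log", {}),
        )


def flag_for_validation(result: TypingResult) -> TypingResult:
    """Set the confirmatory-sequencing flags from the calls themselves.

    homozygous: some locus has a single confirmed allele; close-alleles: some
    locus carries two alleles of the same serotype.  Both classes should be
    validated by targeted sequencing.
    """
    for pair in result.calls.values():
        named = [a for a in pair if a and a != NIL]
        if len(named) == 1:
            result.flags.add("homozygous")
        elif len(named) == 2:
            st = {a.rsplit(":", 1)[0] for a in named}
            if len(st) == 1:
                result.flags.add("close-alleles")
    return result


def _pair_for_report(alleles: tuple[str, ...]) -> tuple[str, str]:
    uniq = sorted(set(alleles))
    if len(uniq) == 1:
        return (uniq[0], NIL)
    return (uniq[0], uniq[1])


def run_typing(
    raw: ArraySignals,
    probeset: ProbeSet,
    catalog: AlleleCatalog,
    serogroups: SerogroupTable | None = None,
    kb: Knowledgebase | None = None,
    config: TypingConfig | None = None,
    cohort_mean: float | None = None,
    freqs: dict[str, float] | None = None,
    uninformative: np.ndarray | None = None,
) -> TypingResult:
    """Type one array end to end.

    ``cohort_mean`` (raw-scale mean over the cohort) enables degradation QC;
    ``freqs`` enables the population-frequency tie-break among reported
    genotypes; ``uninformative`` excludes flat probes from Neg counts when
    the config asks for it.
    """
    config = config or TypingConfig()
    serogroups = serogroups or SerogroupTable({})
    log: dict = {}
    flags: set[str] = set()

    # -- signal processing ------------------------------------------------
    norm = normalize_signals(raw)
    qc = qc_array(norm, cohort_mean, config.degraded_ratio)
    log["qc"] = {"raw_mean": qc.raw_mean, "cohort_mean": qc.cohort_mean, "ratio": qc.ratio}
    if qc.degraded:
        flags.add("degraded")
    if float(norm.values.max()) < config.no_signal_max:
        # array-wide signals too low for any probe to be genuinely positive
        result = TypingResult(
            raw.array_id,
            {l: ("", "") for l in catalog.loci},
            flags | {"no-call"},
            "none",
            log=log,
        )
        return result
    corrected = correct_errors(
        norm, probeset, config.correction_window, config.correction_factor
    )
    thresholds: ThresholdTable | None = None
    if kb is not None and len(kb) > 0:
        thresholds = kb.empirical_thresholds(probeset)
    calls = binarize(corrected, thresholds, config.initial_fraction)
    exclude = uninformative if config.exclude_uninformative else None

    # -- stage 1: serotype determination ----------------------------------
    locus_calls: dict[str, LocusCall] = {}
    negs_by_allele: dict[str, int] = {}
    serotype_scores: dict[str, float] = {}
    max_neg = kb.max_neg() if kb is not None and len(kb) > 0 else {}
    for locus in catalog.loci:
        by_st = locus_allele_negatives(locus, catalog, calls, probeset, exclude)
        for st, d in by_st.items():
            negs_by_allele.update(d)
        lc = serotype_locus(
            locus,
            by_st,
            config.homozygous_margin,
            default_max_difference=config.max_difference,
        )
        locus_calls[locus] = lc
        for s in lc.surviving:
            serotype_scores[s.serotype] = s.neg_st
        log.setdefault("serotypes", {})[locus] = {
            "surviving": lc.surviving_serotypes,
            "homozygous": lc.homozygous_flag,
            "eliminated": [
                {"serotype": st, "rule": rule, "margin": m} for st, rule, m in lc.elimination_log
            ],
        }
    if max_neg:
        exceeded = [
            s.serotype
            for lc in locus_calls.values()
            for s in lc.surviving[:1]
            if s.serotype in max_neg and s.neg_st > max_neg[s.serotype]
        ]
        if len(exceeded) == len(locus_calls):
            return TypingResult(
                raw.array_id,
                {l: ("", "") for l in catalog.loci},
                flags | {"no-call"},
                "none",
                log=log,
            )

    query_serotypes = {l: set(lc.surviving_serotypes) for l, lc in locus_calls.items()}

    # -- template matching -------------------------------------------------
    match: MatchDecision | None = None
    if kb is not None and len(kb) > 0:
        match = kb.match_template(norm, query_serotypes)
        log["template_match"] = {
            "kind": match.kind,
            "template": match.template_id,
            "r": match.r,
            "mismatches": match.mismatches,
        }
        if match.kind == "identity":
            template_genotype = _template_genotype(kb, match.template_id)
            calls_out = {
                l: _pair_for_report(template_genotype[l]) if l in template_genotype else ("", "")
                for l in catalog.loci
            }
            result = TypingResult(
                raw.array_id,
                calls_out,
                flags | {"template-derived"},
                "template",
                matched_template=match.template_id,
                template_r=match.r,
                log=log,
            )
            return flag_for_validation(result)

    # -- stages 2 & 3: genotype determination + ambiguity removal ----------
    weight_thresholds = (
        kb.weight_thresholds(config.weight_threshold) if kb is not None and len(kb) > 0 else None
    )
    candidates: dict[str, list[str]] = {}
    sig = corrected.values
    vectors = []
    for locus, lc in locus_calls.items():
        locus_candidates: list[str] = []
        clusters = serogroups.cluster(lc.surviving_serotypes)
        for group_key, sts in clusters.items():
            allele_negs = {
                a.name: negs_by_allele[a.name]
                for st in sts
                for a in catalog.serotype_members(st)
            }
            vec = build_comparison_vector(
                group_key, sts, catalog, sig, probeset, allele_negs, raw.array_id
            )
            vectors.append(vec)
            selected: list[str] = []
            if kb is not None and len(kb) > 0:
                selected_set, matched = kb.allele_lookup(vec)
                selected = sorted(selected_set)
                log.setdefault("kb_lookup", {})[group_key] = matched
            if not selected:
                avg = dict(zip(vec.alleles, vec.avg_wins))
                negs = {a: int(n) for a, n in zip(vec.alleles, vec.negs)}
                selected = weight_based_selection(
                    vec.alleles, avg, negs, weight_thresholds, config.weight_threshold
                )
                # allele comparison: per serotype keep the most likely allele
                # (alleles tied within the win margin are all retained — that
                # is how a fully masked decoy survives next to the true call)
                weights = vec.weights()
                by_serotype: dict[str, list[str]] = {}
                for a in selected:
                    by_serotype.setdefault(a.rsplit(":", 1)[0], []).append(a)
                selected = [
                    a
                    for st_alleles in by_serotype.values()
                    for a in st_alleles
                    if weights[a] >= max(weights[b] for b in st_alleles) - config.allele_tie_margin
                ]
            locus_candidates.extend(selected)
        candidates[locus] = sorted(set(locus_candidates))
        log.setdefault("candidates", {})[locus] = candidates[locus]
        if len(locus_candidates) > 2:
            flags.add("ambiguous")

    if any(not c for c in candidates.values()):
        # no allele cleared its weight threshold at some locus
        calls_out = {}
        for locus in catalog.loci:
            if candidates[locus]:
                calls_out[locus] = _pair_for_report(tuple(candidates[locus][:2]))
            else:
                calls_out[locus] = ("", "")
        result = TypingResult(
            raw.array_id, calls_out, flags | {"no-call"}, "knowledge-based", log=log
        )
        return flag_for_validation(result)

    reported = resolve_ambiguity(
        candidates, sig, probeset, config.ambiguity_margin
    )
    reported = frequency_tiebreak(reported, freqs)
    if len(reported) > 1:
        flags.add("ambiguous")
    top = reported[0][0]
    calls_out = {l: _pair_for_report(top[l]) for l in catalog.loci}
    result = TypingResult(
        raw.array_id,
        calls_out,
        flags,
        "knowledge-based",
        genotypes=reported[:10],
        log=log,
    )
    result.log["comparison_vectors"] = [v.to_dict() for v in vectors]
    result.log["serotype_scores"] = serotype_scores
    return flag_for_validation(result)


def _template_genotype(kb: Knowledgebase, template_id: str) -> Genotype:
    for t in kb.templates:
        if t.array_id == template_id:
            return t.genotype
    raise KeyError(template_id)


def type_cohort(
    arrays: list[ArraySignals],
    probeset: ProbeSet,
    catalog: AlleleCatalog,
    serogroups: SerogroupTable | None = None,
    kb: Knowledgebase | None = None,
    config: TypingConfig | None = None,
    freqs: dict[str, float] | None = None,
) -> list[TypingResult]:
    """Type a cohort; the cohort raw-signal mean drives degradation QC."""
    cohort_mean = float(np.mean([a.values.mean() for a in arrays])) if len(arrays) > 1 else None
    return [
        run_typing(a, probeset, catalog, serogroups, kb, config, cohort_mean, freqs)
        for a in arrays
    ]
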