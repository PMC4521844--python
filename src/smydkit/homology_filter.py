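"""Candidate acceptance rules for collecting family members from BLAST output.

Sequences enter the family only if they (i) hit the seed query with an
E-value below a strict cutoff (default 1e-7), (ii) align continuously and
co-linearly across the SET-MYND core region of the query, and (iii) are
validated by reciprocal search: their best hit back against the seed
proteome is itself a member of the seed set.

BLAST itself is external; this module consumes 12-column tabular files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seq_io import BlastHitRow


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the acceptance rules.

    ``core`` is ``(ref_id, ref_start, ref_end)`` on the query, 1-based
    inclusive.  "Continuous alignment" is operationalised as: one single HSP
    must cover at least ``min_core_coverage`` of the core interval, and the
    net length discrepancy between its query and subject spans (a proxy for
    large internal indel breaks invisible in tabular output) must not exceed
    ``max_internal_break`` residues.
    """

    core: tuple[str, int, int]
    evalue_max: float = 1e-7
    min_core_coverage: float = 0.9
    max_internal_break: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.min_core_coverage <= 1):
            raise ValueError("min_core_coverage must be in (0, 1]")
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")


@dataclass
class RuleOutcome:
    rule: str          # "evalue" | "continuity" | "reciprocal"
    passed: bool
    detail: str = ""


@dataclass
class CandidateVerdict:
    subject: str
    accepted: bool
    reasons: list[RuleOutcome] = field(default_factory=list)

    def outcome(self, rule: str) -> RuleOutcome | None:
        for r in self.reasons:
            if r.rule == rule:
                return r
        return None


def _hit_sort_key(h: BlastHitRow) -> tuple:
    # lowest evalue, ties by highest bitscore, then subject id, then qstart
    return (h.evalue, -h.bitscore, h.subject, h.qstart)


def _core_coverage(h: BlastHitRow, start: int, end: int) -> float:
    ov = min(h.qend, end) - max(h.qstart, start) + 1
    return max(ov, 0) / (end - start + 1)


def filter_by_evalue_and_continuity(
    hits: list[BlastHitRow], cfg: FilterConfig
) -> list[CandidateVerdict]:
    """Score every subject in ``hits`` against the E-value and continuity rules.

    All hits must share the single query named in ``cfg.core``; the verdict
    list is sorted by subject id and independent of input row order.
    """
    ref_id, start, end = cfg.core
    queries = {h.query for h in hits}
    if queries - {ref_id}:
        raise ValueError(
            f"hits contain query ids {sorted(queries - {ref_id})} != core reference {ref_id!r}"
        )
    by_subject: dict[str, list[BlastHitRow]] = {}
    for h in hits:
        by_subject.setdefault(h.subject, []).append(h)

    verdicts: list[CandidateVerdict] = []
    for subject in sorted(by_subject):
        shits = sorted(by_subject[subject], key=_hit_sort_key)
        best = shits[0]
        ev_ok = best.evalue < cfg.evalue_max
        ev = RuleOutcome("evalue", ev_ok, f"best evalue {best.evalue:g} vs < {cfg.evalue_max:g}")

        cont_ok = False
        cont_detail = "no HSP covers the core"
        for h in shits:
            cov = _core_coverage(h, start, end)
            if cov < cfg.min_core_coverage:
                continue
            q_len = h.qend - h.qstart + 1
            s_len = abs(h.send - h.sstart) + 1
            if abs(q_len - s_len) > cfg.max_internal_break:
                cont_detail = (
                    f"HSP covers {cov:.0%} of core but query/subject span "
                    f"lengths differ by {abs(q_len - s_len)} > {cfg.max_internal_break}"
                )
                continue
            cont_ok = True
            cont_detail = f"single HSP covers {cov:.0%} of core"
            break
        cont = RuleOutcome("continuity", cont_ok, cont_detail)
        verdicts.append(
            CandidateVerdict(subject=subject, accepted=ev_ok and cont_ok, reasons=[ev, cont])
        )
    return verdicts


def reciprocal_best(
    forward: list[CandidateVerdict],
    reverse_hits: list[BlastHitRow],
    seed_set: set[str],
) -> list[CandidateVerdict]:
    """Apply the reciprocal-best rule to forward verdicts.

    ``reverse_hits`` are searches of each candidate subject back against the
    seed proteome (query = the candidate, subject = a seed-proteome protein).
    A candidate passes iff its top reverse hit (lowest evalue, ties by
    highest bitscore, then subject id) is a member of ``seed_set``.
    Candidates with no reverse hits fail with reason "no reciprocal hit".
    """
    by_query: dict[str, list[BlastHitRow]] = {}
    for h in reverse_hits:
        by_query.setdefault(h.query, []).append(h)

    out: list[CandidateVerdict] = []
    for v in forward:
        rhits = sorted(by_query.get(v.subject, []), key=_hit_sort_key)
        if not rhits:
            rec = RuleOutcome("reciprocal", False, "no reciprocal hit")
        else:
            top = rhits[0]
            ok = top.subject in seed_set
            rec = RuleOutcome(
                "reciprocal", ok,
                f"top reverse hit {top.subject} (evalue {top.evalue:g}) "
                + ("in" if ok else "not in") + " seed set",
            )
        reasons = [r for r in v.reasons if r.rule != "reciprocal"] + [rec]
        out.append(
            CandidateVerdict(
                subject=v.subject,
                accepted=all(r.passed for r in reasons),
                reasons=reasons,
            )
        )
    return out


def accepted_ids(verdicts: list[CandidateVerdict]) -> set[str]:
    return {v.subject for v in verdicts if v.accepted}
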