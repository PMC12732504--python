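"""Overrepresentation analysis and the LLM pathway-relevance pipeline.

The top-scoring genes are tested against GMT gene-set collections with a
one-sided hypergeometric test (the standard ORA computation) and
Benjamini–Hochberg FDR control.  Pathway hits are then interpreted by a
two-stage prompt pipeline: a relevance question asked three times, whose
answers are aggregated by a final-verdict prompt.  The language-model
backend is a pluggable callable; the test suite and offline runs use a
deterministic scripted mock.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom


class EnrichmentError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: list[str] | None = None

    def in_universe(self, name: str) -> list[str]:
        members = dict.fromkeys(self.sets[name])  # unique, order-preserving
        if self.universe is None:
            return list(members)
        uni = set(self.universe)
        return [g for g in members if g in uni]


def read_gmt(path: str, universe: Sequence[str] | None = None) -> GeneSetCollection:
    """Parse a GMT file: name, description and members per tab-separated line.

    Empty or short lines are skipped with a warning; duplicate set names are
    an error.  Members outside the universe are retained in the raw listing
    and excluded from counting on demand.
    """
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                warnings.warn(f"{path}:{lineno}: empty line skipped")
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                warnings.warn(f"{path}:{lineno}: malformed line (<3 fields) skipped")
                continue
            name, description, *members = parts
            if name in sets:
                raise EnrichmentError(f"duplicate set name {name!r} at line {lineno}")
            sets[name] = [m for m in members if m]
            desc[name] = description
    return GeneSetCollection(sets, desc, list(universe) if universe is not None else None)


# ---------------------------------------------------------------------------
# ORA
# ---------------------------------------------------------------------------


def ora_test(selected: Sequence[str], universe: Sequence[str], geneset: Sequence[str]):
    """One-sided hypergeometric overrepresentation test.

    P(X ≥ overlap) with population |universe|, successes |geneset ∩ universe|
    and draws |selected ∩ universe|.  Returns ``(p, overlap, set_size,
    n_selected, n_universe)``.
    """
    uni = list(dict.fromkeys(universe))
    if not uni:
        raise EnrichmentError("empty universe")
    uni_set = set(uni)
    sel = [g for g in dict.fromkeys(selected) if g in uni_set]
    if not sel:
        raise EnrichmentError("empty selection after universe intersection")
    gs = {g for g in geneset if g in uni_set}
    overlap = len(gs.intersection(sel))
    N, K, n = len(uni), len(gs), len(sel)
    # P(X >= overlap) = survival function at overlap - 1
    p = float(hypergeom.sf(overlap - 1, N, K, n))
    return min(p, 1.0), overlap, K, n, N


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise EnrichmentError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def ora_analysis(
    selected: Sequence[str],
    collection: GeneSetCollection,
    universe: Sequence[str] | None = None,
    min_set_size: int = 5,
    max_set_size: int = 500,
) -> pd.DataFrame:
    """Run the hypergeometric test for every set, sizes filtered after
    universe intersection, and attach BH-FDR.  Sorted by p ascending."""
    uni = universe if universe is not None else collection.universe
    if uni is None:
        raise EnrichmentError("no background universe provided")
    coll = GeneSetCollection(collection.sets, collection.descriptions, list(uni))
    rows = []
    for name in coll.sets:
        members = coll.in_universe(name)
        if not (min_set_size <= len(members) <= max_set_size):
            continue
        p, overlap, K, n, N = ora_test(selected, uni, members)
        rows.append(
            dict(geneset=name, overlap=overlap, set_size=K, n_selected=n, n_universe=N, p=p)
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(
            columns=["geneset", "overlap", "set_size", "n_selected", "n_universe", "p", "fdr"]
        )
    df["fdr"] = bh_fdr(df["p"].to_numpy())
    return df.sort_values(["p", "geneset"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Prompt pipeline
# ---------------------------------------------------------------------------

PROMPT_STAGE1 = (
    "You have an expert perspective in bioinformatics. Is {pathway} highly "
    "relevant for type 2 diabetes mellitus in Mus musculus? Answer with Yes "
    "or No. Afterwards, describe shortly your explanation for whether the "
    "pathway involves type 2 diabetes, providing references for your claims."
)

PROMPT_STAGE2 = (
    "You have an expert perspective in bioinformatics. Your task is to very "
    "concisely judge whether a pathway is relevant for type 2 diabetes "
    "mellitus (T2D) in Mus musculus. When asked whether {pathway} is highly "
    "relevant for T2D in Mus musculus, these were your answers from three "
    "distinct runs:\n"
    "Answer 1: {answer1}\n"
    "Answer 2: {answer2}\n"
    "Answer 3: {answer3}\n"
    "Now give your final critical verdict with a Yes or No, and describe "
    "very concisely your explanation (with a few sentences at most), using "
    "correct scientific references."
)


def render_prompt_stage1(pathway: str) -> str:
    if not pathway:
        raise EnrichmentError("empty pathway name")
    return PROMPT_STAGE1.format(pathway=pathway)


def render_prompt_stage2(pathway: str, answers: Sequence[str]) -> str:
    if not pathway:
        raise EnrichmentError("empty pathway name")
    if len(answers) != 3:
        raise EnrichmentError(f"stage 2 requires exactly 3 answers, got {len(answers)}")
    return PROMPT_STAGE2.format(
        pathway=pathway, answer1=answers[0], answer2=answers[1], answer3=answers[2]
    )


def parse_verdict(reply: str) -> str:
    """Leading-token Yes/No parse, case- and punctuation-insensitive, with a
    fallback scan for a standalone Yes/No; otherwise "undetermined"."""
    tokens = [t.strip(".,;:!?()[]\"'").lower() for t in reply.split()]
    tokens = [t for t in tokens if t]
    if tokens and tokens[0] in ("yes", "no"):
        return "Yes" if tokens[0] == "yes" else "No"
    for t in tokens:
        if t in ("yes", "no"):
            return "Yes" if t == "yes" else "No"
    return "undetermined"


@dataclass
class LLMVerdict:
    pathway: str
    stage1_answers: list[str]
    verdict: str  # "Yes" | "No" | "undetermined"
    explanation: str
    backend: str


class MockLLMBackend:
    """Deterministic scripted backend for offline runs and tests.

    ``script`` maps a substring of the prompt (typically the pathway name) to
    a canned reply; unmatched prompts get ``default_reply``.
    """

    name = "mock"

    def __init__(self, script: dict[str, str] | None = None, default_reply: str = "Yes. Mock rationale."):
        self.script = script or {}
        self.default_reply = default_reply
        self.calls: list[str] = []

    def __call__(self, prompt: str) -> str:
        self.calls.append(prompt)
        for key, reply in self.script.items():
            if key in prompt:
                return reply
        return self.default_reply


def judge_pathways(
    pathways: Sequence[str],
    backend: Callable[[str], str],
    n_stage1: int = 3,
    max_attempts: int = 3,
) -> list[LLMVerdict]:
    """Two-stage pipeline: the relevance prompt is asked ``n_stage1`` times,
    then the answers are fed to the final-verdict prompt.  Backend failures
    are retried up to ``max_attempts`` times before the pathway is marked
    undetermined.  All raw texts are retained for audit.
    """
    backend_name = getattr(backend, "name", type(backend).__name__)
    verdicts = []
    for pathway in pathways:
        try:
            answers = [
                _call_with_retry(backend, render_prompt_stage1(pathway), max_attempts)
                for _ in range(n_stage1)
            ]
            final = _call_with_retry(
                backend, render_prompt_stage2(pathway, answers), max_attempts
            )
            verdicts.append(
                LLMVerdict(pathway, answers, parse_verdict(final), final, backend_name)
            )
        except _BackendFailure:
            verdicts.append(LLMVerdict(pathway, [], "undetermined", "", backend_name))
    return verdicts


class _BackendFailure(RuntimeError):
    pass


def _call_with_retry(backend, prompt: str, max_attempts: int) -> str:
    last = None
    for _ in range(max_attempts):
        try:
            return backend(prompt)
        except Exception as exc:  # noqa: BLE001 - backend is third-party
            last = exc
    raise _BackendFailure(str(last))


def write_verdicts_jsonl(verdicts: Sequence[LLMVerdict], path: str) -> None:
    with open(path, "w") as fh:
        for v in verdicts:
            fh.write(
                json.dumps(
                    dict(
                        pathway=v.pathway,
                        stage1_answers=v.stage1_answers,
                        verdict=v.verdict,
                        explanation=v.explanation,
                        backend=v.backend,
                    )
                )
                + "\n"
            )
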