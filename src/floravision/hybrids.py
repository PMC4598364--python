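"""Expected vs. unexpected floral colour in polyploid and homoploid hybrids.

A hybrid's colour category (spectral, bee or hummingbird) is *expected* if it
falls in the category of at least one progenitor and *unexpected* if it
differs from both — an unexpected category in a synthetic hybrid, whose
parents are known, is a transgressive phenotype. Chlorophyll in petal tissue
behaves as a dominant character in crossing experiments, so a hybrid is
expected to show chlorophyll whenever at least one progenitor does; a hybrid
lacking it in that situation is unexpected. When both progenitors lack
chlorophyll there is no source of the dominant allele and the expectation is
absence.

For hybrids whose progenitors are known only to section level, expected
states come from ancestral-state reconstruction at the progenitor section's
node (phylo module), and only the spectral category and chlorophyll are
compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .spectra import ChlorophyllCall

__all__ = [
    "HybridTrio",
    "ExpectationVerdict",
    "classify_colour",
    "classify_chlorophyll",
    "audit_table",
    "load_reference_audit",
    "reference_verdicts",
]

CHARACTERS = ("spectral", "bee", "hummingbird", "chlorophyll")


@dataclass(frozen=True)
class HybridTrio:
    """A hybrid and its maternal/paternal progenitor accessions.

    ``section_level`` marks hybrids whose progenitors are resolved only to
    section; their expected states must be supplied from ancestral-state
    reconstruction rather than from extant progenitor accessions.
    """

    hybrid: str
    maternal: str | None = None
    paternal: str | None = None
    section_level: bool = False

    def __post_init__(self) -> None:
        if not self.section_level and not (self.maternal and self.paternal):
            raise ValueError(f"trio for {self.hybrid!r} needs both progenitors or section_level")

    @property
    def progenitors(self) -> tuple[str, ...]:
        return tuple(p for p in (self.maternal, self.paternal) if p)


@dataclass(frozen=True)
class ExpectationVerdict:
    """Observed vs. expected category for one hybrid and one character."""

    character: str
    observed: frozenset[str]
    expected_set: frozenset[str]
    verdict: str

    @property
    def expected(self) -> bool:
        return self.verdict == "expected"


def _verdict(character: str, observed: Iterable[str], expected: Iterable[str]) -> ExpectationVerdict:
    obs = frozenset(observed)
    exp = frozenset(expected)
    verdict = "expected" if obs & exp else "unexpected"
    return ExpectationVerdict(character, obs, exp, verdict)


def classify_colour(
    hybrid_label: str | Iterable[str],
    progenitor_labels: Iterable[str],
    character: str = "spectral",
) -> ExpectationVerdict:
    """Expected iff the hybrid's category matches at least one progenitor's.

    Polymorphic observations (several colour morphs) may be passed as a set;
    the verdict is expected if any observed morph falls in the progenitor
    union.
    """
    observed = {hybrid_label} if isinstance(hybrid_label, str) else set(hybrid_label)
    expected = set(progenitor_labels)
    if not observed or not any(observed):
        raise ValueError("missing hybrid category label")
    if not expected:
        raise ValueError("empty progenitor category set")
    return _verdict(character, observed, expected)


def classify_chlorophyll(
    hybrid: ChlorophyllCall | str,
    progenitors: Sequence[ChlorophyllCall | str],
) -> ExpectationVerdict:
    """Dominance-model chlorophyll expectation.

    If any progenitor carries chlorophyll ('C') the expected state is 'C';
    only if all progenitors lack it is the expectation 'N'.
    """
    obs = hybrid.state if isinstance(hybrid, ChlorophyllCall) else str(hybrid)
    prog = [p.state if isinstance(p, ChlorophyllCall) else str(p) for p in progenitors]
    if not prog:
        raise ValueError("empty progenitor set")
    expected = {"C"} if "C" in prog else {"N"}
    return _verdict("chlorophyll", {obs}, expected)


def audit_table(
    trios: Sequence[HybridTrio],
    categories: Mapping[str, Mapping[str, str | set[str]]],
    chlorophyll: Mapping[str, ChlorophyllCall | str] | None = None,
    section_expectations: Mapping[str, Mapping[str, set[str]]] | None = None,
) -> pd.DataFrame:
    """Audit every hybrid x character; one verdict row each.

    ``categories`` maps character -> accession -> label (or set of labels for
    polymorphic accessions); ``chlorophyll`` maps accession -> call/state.
    ``section_expectations`` supplies expected label sets per character for
    section-level trios. Accessions missing a category are reported in rows
    with verdict ``uncategorized`` rather than silently dropped.
    """
    chlorophyll = chlorophyll or {}
    section_expectations = section_expectations or {}
    rows = []
    for trio in trios:
        wanted = ("spectral", "chlorophyll") if trio.section_level else CHARACTERS
        for character in wanted:
            if character == "chlorophyll":
                obs = chlorophyll.get(trio.hybrid)
                if trio.section_level:
                    exp = section_expectations.get(trio.hybrid, {}).get("chlorophyll")
                    prog_states = sorted(exp) if exp else None
                else:
                    prog_states = [chlorophyll.get(p) for p in trio.progenitors]
                    if any(p is None for p in prog_states):
                        prog_states = None
                if obs is None or prog_states is None:
                    rows.append(_problem_row(trio.hybrid, character))
                    continue
                v = classify_chlorophyll(obs, prog_states)
            else:
                table = categories.get(character, {})
                obs = table.get(trio.hybrid)
                if trio.section_level:
                    exp = section_expectations.get(trio.hybrid, {}).get(character)
                else:
                    exp = set()
                    for p in trio.progenitors:
                        lab = table.get(p)
                        if lab is None:
                            exp = None
                            break
                        exp |= lab if isinstance(lab, (set, frozenset)) else {lab}
                if obs is None or not exp:
                    rows.append(_problem_row(trio.hybrid, character))
                    continue
                v = classify_colour(obs if isinstance(obs, (set, frozenset)) else str(obs), exp, character)
            rows.append(
                {
                    "hybrid": trio.hybrid,
                    "character": v.character,
                    "observed": "|".join(sorted(v.observed)),
                    "expected": "|".join(sorted(v.expected_set)),
                    "verdict": v.verdict,
                }
            )
    return pd.DataFrame(rows, columns=["hybrid", "character", "observed", "expected", "verdict"])


def _problem_row(hybrid: str, character: str) -> dict:
    return {
        "hybrid": hybrid,
        "character": character,
        "observed": "",
        "expected": "",
        "verdict": "uncategorized",
    }


def summarize_audit(audit: pd.DataFrame) -> pd.DataFrame:
    """Counts of expected/unexpected verdicts per character."""
    ok = audit[audit["verdict"] != "uncategorized"]
    return ok.groupby(["character", "verdict"]).size().unstack(fill_value=0)


# ---------------------------------------------------------------------------
# Published reference table


def load_reference_audit() -> pd.DataFrame:
    """The published observed/expected colour categories for Nicotiana hybrids.

    One row per hybrid accession with observed and expected ('|'-joined)
    category labels for the spectral, bee, hummingbird and chlorophyll
    characters, plus the published unexpected flags. Bee and hummingbird
    columns are empty where progenitors are known only to section level.
    """
    with resources.files("floravision.data").joinpath("hybrid_colour_reference.csv").open() as fh:
        return pd.read_csv(fh, keep_default_na=False)


def reference_verdicts(reference: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute every verdict in the published reference from its raw labels.

    Applies the membership rule (and, for chlorophyll, the dominance rule's
    already-resolved expected state) to the observed/expected label sets and
    returns the table with a recomputed ``verdict`` per character, alongside
    the published flag, for direct comparison.
    """
    ref = load_reference_audit() if reference is None else reference
    rows = []
    for _, row in ref.iterrows():
        for character in CHARACTERS:
            col = character
            obs_raw = row[f"{col}_observed"]
            exp_raw = row[f"{col}_expected"]
            if not obs_raw or not exp_raw:
                continue
            observed = set(obs_raw.split("|"))
            expected = set(exp_raw.split("|"))
            v = _verdict(character, observed, expected)
            rows.append(
                {
                    "species": row["species"],
                    "character": character,
                    "observed": obs_raw,
                    "expected": exp_raw,
                    "verdict": v.verdict,
                    "published_unexpected": bool(int(row[f"{col}_unexpected"])),
                }
            )
    return pd.DataFrame(rows)
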