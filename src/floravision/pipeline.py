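"""Stage functions joining the modules into a reproducible pipeline.

Each stage reads and writes plain CSV/JSON/Newick files with stable names,
so a study can be driven from the shell (see :mod:`floravision.cli`) or from
Python. Stages: preprocess -> loci -> cluster -> classify-hybrids ->
mantel / asr.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import categories as cat
from . import hybrids as hyb
from . import phylo
from .spectra import (
    STANDARD_GRID,
    ChlorophyllCall,
    Spectrum,
    average_replicates,
    detect_chlorophyll,
    normalize_integral,
    smooth,
    write_chlorophyll_calls,
    write_spectra,
)
from .synthetic_data import make_leaf_background
from .vision import bee_visual_system, hummingbird_visual_system, project_library

__all__ = [
    "load_wide_spectra",
    "preprocess",
    "loci",
    "cluster",
    "classify_hybrids",
    "mantel",
    "asr",
]

_REPLICATE_RE = re.compile(r"^(?P<accession>.+?)__r\d+$")


def load_wide_spectra(path: str | Path) -> dict[str, list[Spectrum]]:
    """Read a wide spectra CSV; columns ``<accession>`` or ``<accession>__r<k>``."""
    df = pd.read_csv(path)
    wl = df.iloc[:, 0].to_numpy(float)
    groups: dict[str, list[Spectrum]] = {}
    for col in df.columns[1:]:
        m = _REPLICATE_RE.match(col)
        accession = m.group("accession") if m else col
        groups.setdefault(accession, []).append(
            Spectrum(wl, df[col].to_numpy(float), accession_id=accession)
        )
    return groups


def preprocess(
    spectra_path: str | Path,
    out_dir: str | Path,
    window_nm: int = 9,
    passes: int = 3,
) -> tuple[dict[str, Spectrum], dict[str, ChlorophyllCall]]:
    """Average replicates, smooth, and call chlorophyll for every accession.

    Writes ``processed_spectra.csv`` (wide) and ``chlorophyll.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    groups = load_wide_spectra(spectra_path)
    processed: dict[str, Spectrum] = {}
    calls: dict[str, ChlorophyllCall] = {}
    for accession, reps in groups.items():
        s = smooth(average_replicates(reps), window_nm=window_nm, passes=passes)
        processed[accession] = s
        calls[accession] = detect_chlorophyll(s)
    write_spectra(list(processed.values()), out / "processed_spectra.csv")
    write_chlorophyll_calls(calls, out / "chlorophyll.json")
    return processed, calls


def loci(
    processed: Mapping[str, Spectrum] | str | Path,
    space: str,
    out_dir: str | Path,
    background: Spectrum | None = None,
) -> pd.DataFrame:
    """Project processed spectra into a colour space; writes ``loci_<space>.csv``.

    ``space`` is ``bee`` (colour hexagon) or ``bird`` (3-D hummingbird
    space). The adapting background defaults to the synthetic average leaf.
    """
    if not isinstance(processed, Mapping):
        groups = load_wide_spectra(processed)
        processed = {a: reps[0] for a, reps in groups.items()}
    bg = background or smooth(make_leaf_background())
    if space == "bee":
        vs = bee_visual_system(bg)
    elif space == "bird":
        vs = hummingbird_visual_system(bg)
    else:
        raise ValueError(f"unknown space {space!r} (use 'bee' or 'bird')")
    table = project_library(list(processed.values()), vs)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / f"loci_{space}.csv", index=False, float_format="%.6g")
    return table


def cluster(
    source: Mapping[str, Spectrum] | pd.DataFrame | str | Path,
    space: str,
    out_dir: str | Path,
    k: int | None = None,
    height: float | None = None,
) -> cat.CategoryAssignment:
    """Cluster into colour categories; writes category table, merge trace, Newick.

    ``space='spectral'`` clusters integral-normalised 401-point curves;
    ``'bee'``/``'bird'`` cluster the (x, y)/(x, y, z) loci (pass the loci
    table or its CSV path as ``source``).
    """
    if space == "spectral":
        if isinstance(source, (str, Path)):
            groups = load_wide_spectra(source)
            source = {a: reps[0] for a, reps in groups.items()}
        rows = pd.DataFrame(
            {a: normalize_integral(s).reflectance for a, s in source.items()}
        ).T
    elif space in {"bee", "bird"}:
        if isinstance(source, (str, Path)):
            source = pd.read_csv(source)
        coords = ["x", "y"] if space == "bee" else ["x", "y", "z"]
        rows = source.set_index("accession")[coords]
    else:
        raise ValueError(f"unknown space {space!r}")
    assignment, dendrogram = cat.categorize(rows, k=k, height=height)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    assignment.as_series().rename_axis("accession").reset_index().assign(space=space).to_csv(
        out / f"categories_{space}.csv", index=False
    )
    dendrogram.merge_table().to_csv(out / f"merges_{space}.csv", index=False)
    (out / f"dendrogram_{space}.nwk").write_text(dendrogram.to_newick())
    return assignment


def classify_hybrids(
    trio_path: str | Path,
    category_tables: Mapping[str, Mapping[str, str]],
    chlorophyll: Mapping[str, ChlorophyllCall | str],
    out_dir: str | Path,
) -> pd.DataFrame:
    """Audit hybrids against progenitors; writes verdicts CSV and a summary JSON."""
    trios_df = pd.read_csv(trio_path)
    trios = [
        hyb.HybridTrio(
            hybrid=str(r["hybrid"]),
            maternal=str(r["maternal"]) if pd.notna(r["maternal"]) else None,
            paternal=str(r["paternal"]) if pd.notna(r["paternal"]) else None,
            section_level=bool(r.get("section_level", False)),
        )
        for _, r in trios_df.iterrows()
    ]
    audit = hyb.audit_table(trios, category_tables, chlorophyll)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    audit.to_csv(out / "hybrid_verdicts.csv", index=False)
    summary = hyb.summarize_audit(audit)
    (out / "hybrid_summary.json").write_text(summary.to_json(indent=2))
    return audit


def mantel(
    tree_sample_path: str | Path,
    features: pd.DataFrame,
    out_dir: str | Path,
    n_perm: int = 10000,
    alpha: float = 0.05,
    seed: int | None = None,
    duplicates: Mapping[str, int] | None = None,
) -> phylo.MantelSummary:
    """Phylogenetic-signal Mantel tests of a feature table over a tree sample.

    ``features``: numeric rows indexed by taxon (e.g. normalised spectra or
    colour loci). Writes ``mantel_<n>.json`` style summary to ``out_dir``.
    """
    trees = phylo.read_tree_sample(tree_sample_path)
    trait_d = cat.euclidean_distances(features)
    summary = phylo.mantel_over_trees(
        trees, trait_d, duplicates=duplicates, n_perm=n_perm, seed=seed, alpha=alpha
    )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "mantel_summary.json").write_text(
        json.dumps(
            {
                "mean_p": summary.mean_p,
                "sd_p": summary.sd_p,
                "pct_significant": summary.pct_significant,
                "n_trees": summary.n_trees,
                "n_skipped": summary.n_skipped,
                "n_perm": n_perm,
                "alpha": alpha,
            },
            indent=2,
        )
    )
    return summary


def asr(
    tree_sample_path: str | Path,
    consensus_path: str | Path,
    traits: Mapping[str, str],
    out_dir: str | Path,
    alphabet: list[str] | None = None,
) -> phylo.ASROverTrees:
    """Parsimony ASR traced over a tree sample, summarised on the consensus tree.

    Writes ``asr_frequencies.json`` with per-node state frequencies and
    coverage (nodes keyed by sorted tip-label clades).
    """
    trees = phylo.read_tree_sample(tree_sample_path)
    consensus = phylo.read_newick(consensus_path)
    result = phylo.asr_over_trees(trees, traits, consensus, alphabet=alphabet)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "alphabet": list(result.alphabet),
        "nodes": [
            {
                "clade": sorted(key),
                "frequencies": result.frequencies[key],
                "coverage": result.coverage[key],
            }
            for key in result.frequencies
        ],
        "parsimony_lengths": list(result.parsimony_lengths),
    }
    (out / "asr_frequencies.json").write_text(json.dumps(payload, indent=2))
    return result
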