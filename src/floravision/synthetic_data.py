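"""Synthetic study generator: flower spectra, trees, traits and hybrid trios.

Flower reflectance is modelled Beer–Lambert style: a flat scattering baseline
attenuated by Gaussian absorption bands,

    R(λ) = baseline · exp(−Σ_i depth_i · exp(−(λ−c_i)²/2w_i²)) + ε,

with additive Gaussian measurement noise ε clipped at zero. The band roster
mimics the pigments that shape real petal spectra: anthocyanins absorb in
the green (~500–560 nm), giving the pink/magenta double-peak (one
reflectance maximum in the blue, one in the red); chlorophyll absorbs near
430 and 675 nm (the 675 nm minimum is the diagnostic of chlorophyll in
petal tissue); carotenoids absorb below 500 nm (the yellow step);
UV-absorbing flavonoids darken the spectrum below 400 nm. This is a shape
model, not radiative transfer: gloss, structural colour and petal
microstructure are outside it.

Trees come from a Yule (pure-birth) simulator, categorical colour states
from a symmetric continuous-time Markov (Mk) walk down the tree, and
hybrid accessions follow configurable inheritance rules (maternal,
paternal or transgressive). Everything is driven by one master seed and is
bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .spectra import STANDARD_GRID, Spectrum
from .vision import d65_illuminant

__all__ = [
    "PigmentProfile",
    "SimulationConfig",
    "DEFAULT_CLASS_PROFILES",
    "make_illuminant",
    "make_leaf_background",
    "simulate_flower_spectrum",
    "simulate_replicates",
    "simulate_yule_tree",
    "simulate_mk_trait",
    "simulate_brownian_trait",
    "make_study",
]


@dataclass(frozen=True)
class PigmentProfile:
    """Absorption-band recipe for one flower colour class.

    ``bands`` are (center_nm, width_nm, absorbance_depth) triples;
    ``noise_sd`` is the replicate measurement noise in reflectance units.
    """

    name: str
    baseline_reflectance: float = 0.7
    bands: tuple[tuple[float, float, float], ...] = ()
    noise_sd: float = 0.003

    def __post_init__(self) -> None:
        if not (0 < self.baseline_reflectance <= 1.2):
            raise ValueError("baseline must be a positive reflectance fraction")
        for c, w, d in self.bands:
            if w <= 0 or d < 0:
                raise ValueError("band widths must be > 0 and depths >= 0")

    @property
    def has_chlorophyll(self) -> bool:
        return any(abs(c - 675.0) < 10.0 and d > 0 for c, _, d in self.bands)

    def mean_curve(self) -> np.ndarray:
        absorbance = np.zeros_like(STANDARD_GRID)
        for c, w, d in self.bands:
            absorbance += d * np.exp(-((STANDARD_GRID - c) ** 2) / (2.0 * w**2))
        return self.baseline_reflectance * np.exp(-absorbance)


#: Named colour-class recipes mirroring the human-colour categories seen in
#: Nicotiana petals (white, UV-white, pink, magenta, red, yellow, green,
#: dark green). Band positions follow the pigments — UV-absorbing flavonoids
#: near 330 nm, anthocyanins in the green (pink/magenta double-peak),
#: carotenoids below 500 nm, chlorophyll at 430/675 nm; depths are this
#: generator's own calibration, chosen so the classes differ in normalised
#: *shape* (concentration differences are removed by integral
#: normalisation before clustering).
DEFAULT_CLASS_PROFILES: dict[str, PigmentProfile] = {
    "white": PigmentProfile("white", 0.75, ((330.0, 40.0, 2.5),)),
    "uv_white": PigmentProfile("uv_white", 0.75, ()),
    "pink": PigmentProfile("pink", 0.70, ((330.0, 40.0, 2.5), (515.0, 35.0, 1.6))),
    "magenta": PigmentProfile("magenta", 0.65, ((330.0, 40.0, 2.5), (560.0, 50.0, 3.2))),
    "red": PigmentProfile("red", 0.60, ((330.0, 40.0, 2.0), (470.0, 70.0, 2.8))),
    "yellow": PigmentProfile("yellow", 0.80, ((330.0, 40.0, 2.0), (430.0, 50.0, 2.4))),
    "green": PigmentProfile(
        "green", 0.55, ((330.0, 40.0, 2.0), (430.0, 30.0, 1.2), (675.0, 12.0, 1.0))
    ),
    "dark_green": PigmentProfile(
        "dark_green",
        0.40,
        ((330.0, 40.0, 2.5), (450.0, 40.0, 2.2), (560.0, 45.0, 1.0), (675.0, 12.0, 2.2)),
    ),
}


def make_illuminant(kind: str = "D65_bundled") -> np.ndarray:
    """Relative irradiance on the standard grid, normalised to mean 1."""
    if kind == "flat":
        curve = np.ones_like(STANDARD_GRID)
    elif kind == "D65_bundled":
        curve = d65_illuminant()
    else:
        raise ValueError(f"unknown illuminant kind {kind!r}")
    return curve / curve.mean()


def make_leaf_background(chl_depth: float = 0.8) -> Spectrum:
    """Synthetic average-leaf reflectance: the adapting background.

    Green-reflecting (peak near 550 nm), dark in the UV/blue, with a strong
    chlorophyll minimum at 675 nm of configurable depth.
    """
    absorbance = (
        2.0 * np.exp(-((STANDARD_GRID - 340.0) ** 2) / (2.0 * 50.0**2))
        + 1.6 * np.exp(-((STANDARD_GRID - 450.0) ** 2) / (2.0 * 45.0**2))
        + 0.9 * np.exp(-((STANDARD_GRID - 610.0) ** 2) / (2.0 * 40.0**2))
        + chl_depth * np.exp(-((STANDARD_GRID - 675.0) ** 2) / (2.0 * 14.0**2))
    )
    reflectance = 0.5 * np.exp(-absorbance)
    return Spectrum(STANDARD_GRID.copy(), reflectance, accession_id="leaf", taxon="background")


def simulate_flower_spectrum(
    profile: PigmentProfile,
    seed: int | np.random.Generator | None = None,
) -> tuple[Spectrum, dict]:
    """One noisy reflectance measurement plus its ground-truth labels."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    clean = profile.mean_curve()
    noisy = clean + rng.normal(0.0, profile.noise_sd, size=clean.size) if profile.noise_sd > 0 else clean
    noisy = np.clip(noisy, 0.0, None)
    truth = {
        "class": profile.name,
        "chlorophyll": profile.has_chlorophyll,
        "bands": [list(b) for b in profile.bands],
    }
    return Spectrum(STANDARD_GRID.copy(), noisy, accession_id=profile.name, taxon=profile.name), truth


def simulate_replicates(
    profile: PigmentProfile,
    accession_id: str,
    n_replicates: int = 3,
    seed: int | np.random.Generator | None = None,
    taxon: str = "",
) -> list[Spectrum]:
    """Replicate measurements sharing a profile, differing only in noise."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for _ in range(n_replicates):
        s, _truth = simulate_flower_spectrum(profile, rng)
        out.append(replace(s, accession_id=accession_id, taxon=taxon or profile.name))
    return out


# ---------------------------------------------------------------------------
# Trees and traits


def simulate_yule_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    seed: int | np.random.Generator | None = None,
    prefix: str = "t",
    taxon_namespace: dendropy.TaxonNamespace | None = None,
) -> dendropy.Tree:
    """Pure-birth tree: exponential waiting times, uniform lineage splitting."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ns = taxon_namespace or dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = True
    active = [tree.seed_node]
    birth_time = {tree.seed_node: 0.0}
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        parent = active.pop(rng.integers(len(active)))
        parent.edge.length = t - birth_time[parent] if parent.parent_node is not None else None
        for _ in range(2):
            child = parent.new_child()
            birth_time[child] = t
            active.append(child)
    t_end = t + rng.exponential(1.0 / (birth_rate * len(active)))
    for i, leaf in enumerate(sorted(active, key=lambda n: birth_time[n])):
        leaf.edge.length = t_end - birth_time[leaf]
        leaf.taxon = ns.require_taxon(f"{prefix}{i + 1}")
    if tree.seed_node.edge.length is None:
        tree.seed_node.edge.length = 0.0
    return tree


def jitter_branch_lengths(
    tree: dendropy.Tree,
    rel_sd: float = 0.2,
    seed: int | np.random.Generator | None = None,
) -> dendropy.Tree:
    """Copy of a tree with branch lengths perturbed by lognormal factors.

    A cheap stand-in for posterior topological/branch-length uncertainty
    when only one true tree exists (synthetic; keeps the topology fixed).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = tree.clone(depth=1)
    for edge in out.preorder_edge_iter():
        if edge.length:
            edge.length = float(edge.length) * float(rng.lognormal(0.0, rel_sd))
    return out


def simulate_mk_trait(
    tree: dendropy.Tree,
    states: Sequence[str],
    rate: float = 0.3,
    seed: int | np.random.Generator | None = None,
    root_state: str | None = None,
) -> tuple[dict[str, str], dict, int]:
    """Symmetric Mk evolution of a categorical state down the tree.

    Events occur at ``rate`` per unit branch length; at each event the state
    jumps to one of the other states uniformly. Returns (tip states, true
    state at every node keyed by clade tip set, total number of simulated
    changes).
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    states = list(states)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root = tree.seed_node
    node_state = {root: root_state if root_state is not None else states[rng.integers(len(states))]}
    n_changes = 0
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        state = node_state[node.parent_node]
        length = float(node.edge.length or 0.0)
        if rate > 0 and length > 0:
            t = rng.exponential(1.0 / rate)
            while t < length:
                others = [s for s in states if s != state]
                state = others[rng.integers(len(others))]
                n_changes += 1
                t += rng.exponential(1.0 / rate)
        node_state[node] = state
    tips = {n.taxon.label: node_state[n] for n in tree.leaf_node_iter()}
    truth = {
        frozenset(l.taxon.label for l in n.leaf_iter()): node_state[n]
        for n in tree.preorder_node_iter()
    }
    return tips, truth, n_changes


def simulate_brownian_trait(
    tree: dendropy.Tree,
    n_dims: int = 3,
    sigma: float = 1.0,
    seed: int | np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Brownian-motion trait vectors at the tips (independent dimensions)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = {tree.seed_node: np.zeros(n_dims)}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        length = float(node.edge.length or 0.0)
        step = rng.normal(0.0, sigma * np.sqrt(max(length, 0.0)), size=n_dims)
        values[node] = values[node.parent_node] + step
    return {n.taxon.label: values[n] for n in tree.leaf_node_iter()}


# ---------------------------------------------------------------------------
# Whole-study bundles


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of a full synthetic study.

    Defaults mirror the scale of the motivating study: ~60 accessions
    (classes × taxa × accessions) measured in 3 replicates, a Yule tree over
    the diploid taxa, an Mk-evolving colour state, and a handful of hybrid
    accessions with known progenitors.
    """

    class_names: tuple[str, ...] = ("white", "pink", "yellow", "green")
    taxa_per_class: int = 5
    replicates: int = 3
    n_hybrids: int = 6
    transgressive_prob: float = 0.25
    chlorophyll_loss_prob: float = 0.3
    birth_rate: float = 1.0
    mk_rate: float = 0.3
    n_posterior_trees: int = 10
    noise_sd: float = 0.003
    master_seed: int = 0


@dataclass(frozen=True)
class StudyBundle:
    """In-memory handle on a generated study with its ground truth."""

    root: Path
    spectra_path: Path
    metadata_path: Path
    trio_path: Path
    consensus_tree_path: Path
    tree_sample_path: Path
    trait_path: Path
    manifest_path: Path
    manifest: dict


def make_study(config: SimulationConfig, out_dir: str | Path) -> StudyBundle:
    """Generate a full on-disk study bundle exercising every pipeline stage.

    Writes: a wide CSV of replicate spectra (columns ``accession``, rows
    wavelengths; replicates as ``<accession>__r<k>``), accession metadata,
    a hybrid trio table, a consensus Newick tree over the diploid taxa, a
    posterior-like Newick tree sample, a trait table of true colour classes,
    and a JSON manifest of all ground truth (classes, hybrid rules applied,
    true ancestral states, seeds).
    """
    rng = np.random.default_rng(config.master_seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    profiles = {name: replace(DEFAULT_CLASS_PROFILES[name], noise_sd=config.noise_sd)
                for name in config.class_names}

    # --- diploid taxa with class assignments
    taxa = []
    taxon_class = {}
    for cls in config.class_names:
        for i in range(config.taxa_per_class):
            taxon = f"{cls}_{i + 1}"
            taxa.append(taxon)
            taxon_class[taxon] = cls

    # --- hybrids: pick progenitor pairs; inherit or transgress
    hybrids = []
    hybrid_rules = {}
    for h in range(config.n_hybrids):
        maternal, paternal = (taxa[i] for i in rng.choice(len(taxa), size=2, replace=False))
        name = f"hybrid_{h + 1}"
        if rng.random() < config.transgressive_prob:
            outside = [c for c in config.class_names
                       if c not in (taxon_class[maternal], taxon_class[paternal])]
            cls = outside[rng.integers(len(outside))] if outside else taxon_class[maternal]
            rule = "transgressive"
        else:
            rule = "maternal" if rng.random() < 0.5 else "paternal"
            cls = taxon_class[maternal if rule == "maternal" else paternal]
        profile = profiles[cls]
        if profile.has_chlorophyll and rng.random() < config.chlorophyll_loss_prob:
            bands = tuple(b for b in profile.bands if not (abs(b[0] - 675.0) < 10.0 or abs(b[0] - 430.0) < 10.0))
            profile = replace(profile, name=f"{cls}_chl_loss", bands=bands)
            rule += "+chl_loss"
        hybrids.append(name)
        taxon_class[name] = profile.name
        profiles[profile.name] = profile
        hybrid_rules[name] = {"maternal": maternal, "paternal": paternal, "rule": rule,
                              "class": profile.name}

    # --- spectra (replicates per accession; accession == taxon here)
    import pandas as pd

    wide = {"wavelength_nm": STANDARD_GRID}
    truth_spectra = {}
    for taxon in taxa + hybrids:
        profile = profiles[taxon_class[taxon]]
        reps = simulate_replicates(profile, taxon, config.replicates, rng, taxon=taxon)
        for k, s in enumerate(reps):
            wide[f"{taxon}__r{k + 1}"] = s.reflectance
        truth_spectra[taxon] = {"class": profile.name, "chlorophyll": profile.has_chlorophyll}
    spectra_path = out / "spectra_wide.csv"
    pd.DataFrame(wide).to_csv(spectra_path, index=False, float_format="%.6g")

    metadata_path = out / "metadata.csv"
    meta_rows = [
        {"accession_id": t, "taxon": t, "role": "diploid", "maternal": "", "paternal": ""}
        for t in taxa
    ] + [
        {"accession_id": h, "taxon": h, "role": "polyploid",
         "maternal": hybrid_rules[h]["maternal"], "paternal": hybrid_rules[h]["paternal"]}
        for h in hybrids
    ]
    pd.DataFrame(meta_rows).to_csv(metadata_path, index=False)

    trio_path = out / "trios.csv"
    pd.DataFrame(
        [{"hybrid": h, "maternal": hybrid_rules[h]["maternal"],
          "paternal": hybrid_rules[h]["paternal"], "section_level": False} for h in hybrids]
    ).to_csv(trio_path, index=False)

    # --- tree over diploid taxa + Mk colour state
    tree = simulate_yule_tree(len(taxa), config.birth_rate, rng, prefix="tmp")
    for leaf, taxon in zip(
        sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label), sorted(taxa)
    ):
        leaf.taxon.label = taxon
    consensus_tree_path = out / "consensus.nwk"
    write_newick_text = tree.as_string(schema="newick", suppress_rooting=True)
    consensus_tree_path.write_text(write_newick_text)
    sample_trees = [jitter_branch_lengths(tree, 0.2, rng) for _ in range(config.n_posterior_trees)]
    tree_sample_path = out / "tree_sample.nwk"
    tree_sample_path.write_text(
        "".join(t.as_string(schema="newick", suppress_rooting=True) for t in sample_trees)
    )

    tips, true_nodes, n_changes = simulate_mk_trait(
        tree, list(config.class_names), config.mk_rate, rng
    )
    trait_path = out / "traits.csv"
    pd.DataFrame(
        [{"taxon": t, "colour_class": taxon_class[t], "mk_state": tips[t]} for t in taxa]
    ).to_csv(trait_path, index=False)

    manifest = {
        "master_seed": config.master_seed,
        "class_names": list(config.class_names),
        "taxa": taxa,
        "hybrids": hybrid_rules,
        "spectra_truth": truth_spectra,
        "mk_tip_states": tips,
        "mk_true_node_states": {"|".join(sorted(k)): v for k, v in true_nodes.items()},
        "mk_n_changes": n_changes,
        "files": {
            "spectra": spectra_path.name,
            "metadata": metadata_path.name,
            "trios": trio_path.name,
            "consensus_tree": consensus_tree_path.name,
            "tree_sample": tree_sample_path.name,
            "traits": trait_path.name,
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return StudyBundle(
        out, spectra_path, metadata_path, trio_path, consensus_tree_path,
        tree_sample_path, trait_path, manifest_path, manifest,
    )
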