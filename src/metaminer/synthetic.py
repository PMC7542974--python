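"""Synthetic data generation for the whole toolkit.

Every input artifact — peak tables with planted group effects, injection
drift and left-censored missingness; compound/spectral libraries; reaction
pair databases; pathway libraries; and coupled microbiome tables — can be
generated deterministically from a seed, with a truth record that downstream
recovery tests can score against.

Intensities follow a log-normal model with multiplicative noise, the usual
behavior of integrated MS peak areas; group effects are additive on the log
scale in units of the log-scale SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import CompoundLibrary, LibraryEntry
from .correlation import MicrobeTable
from .pathway import PathwayGraph, PathwayLibrary
from .reaction_ratios import ReactionPair, ReactionPairDB
from .tables_io import PeakTable, SampleMetadata

__all__ = ["SimDesign", "simulate_peak_table", "simulate_coupled_microbiome",
           "simulate_pathway_library", "simulate_compound_library"]


@dataclass
class SimDesign:
    """Design of a two-group simulated metabolomics study.

    effect_size is in units of the log-scale SD; drift_slope is the
    fractional intensity change per injection; qc_every inserts a pooled QC
    sample every so many injections (0 = none); censor_left concentrates
    missingness below the per-variable detection quantile.
    """

    n_per_group: int = 30
    n_variables: int = 200
    n_informative: int = 10
    effect_size: float = 1.5
    missing_rate: float = 0.0
    censor_left: bool = True
    drift_slope: float = 0.0
    qc_every: int = 0
    confounder_strength: float = 0.0
    log_sd: float = 0.6
    log_mean: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.n_informative > self.n_variables:
            raise ValueError("n_informative exceeds n_variables")


def simulate_peak_table(design: SimDesign
                        ) -> tuple[PeakTable, SampleMetadata, dict]:
    """Simulate a two-group peak table with known differential variables.

    Returns (table, metadata, truth) where truth records the informative
    variable ids and their log-scale effects.
    """
    rng = np.random.default_rng(design.seed)
    n_study = 2 * design.n_per_group
    p = design.n_variables

    groups = ["A"] * design.n_per_group + ["B"] * design.n_per_group
    order = rng.permutation(n_study)  # randomized injection sequence

    base_mean = design.log_mean + rng.normal(0, 1.5, size=p)
    log_int = rng.normal(0, design.log_sd, size=(n_study, p)) + base_mean

    informative = rng.choice(p, size=design.n_informative, replace=False)
    signs = rng.choice([-1.0, 1.0], size=design.n_informative)
    effects = signs * design.effect_size * design.log_sd
    is_b = np.array([g == "B" for g in groups])
    for idx, eff in zip(informative, effects):
        log_int[is_b, idx] += eff

    if design.confounder_strength > 0:
        confounder = rng.normal(0, 1, size=n_study)
        conf_vars = rng.choice(p, size=max(1, p // 10), replace=False)
        for idx in conf_vars:
            log_int[:, idx] += (design.confounder_strength * design.log_sd
                                * confounder)
    else:
        confounder = np.zeros(n_study)

    sample_ids = [f"S{i+1:03d}" for i in range(n_study)]
    injection = np.empty(n_study, dtype=int)
    injection[order] = np.arange(1, n_study + 1)

    rows = {"group": groups, "injection_order": injection,
            "is_qc": [False] * n_study, "confounder": confounder}
    frame = pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample_id"))

    if design.qc_every > 0:
        pooled = log_int.mean(axis=0)
        max_order = int(frame["injection_order"].max())
        qc_orders = list(range(design.qc_every, max_order + 1, design.qc_every))
        qc_rows, qc_ids = [], []
        for i, o in enumerate(qc_orders):
            qc_ids.append(f"QC{i+1:02d}")
            qc_rows.append(pooled + rng.normal(0, design.log_sd / 4, size=p))
        # shift study injections to interleave QCs deterministically
        all_orders = np.concatenate([frame["injection_order"].to_numpy(),
                                     np.array(qc_orders) + 0.5])
        rank = np.argsort(np.argsort(all_orders)) + 1
        frame["injection_order"] = rank[:n_study]
        qc_frame = pd.DataFrame({
            "group": "QC", "injection_order": rank[n_study:],
            "is_qc": True, "confounder": 0.0},
            index=pd.Index(qc_ids, name="sample_id"))
        frame = pd.concat([frame, qc_frame])
        log_int = np.vstack([log_int, np.array(qc_rows)])
        sample_ids = sample_ids + qc_ids

    intensities = np.exp(log_int)
    if design.drift_slope != 0:
        drift = 1.0 + design.drift_slope * frame["injection_order"].to_numpy()
        intensities = intensities * drift[:, None]

    var_ids = [f"V{j+1:04d}" for j in range(p)]
    data = pd.DataFrame(intensities, index=sample_ids, columns=var_ids)

    if design.missing_rate > 0:
        if design.censor_left:
            # missing below the per-variable missing_rate quantile
            thresholds = data.quantile(design.missing_rate, axis=0)
            mask = data.lt(thresholds, axis=1)
        else:
            mask = pd.DataFrame(
                rng.random(data.shape) < design.missing_rate,
                index=data.index, columns=data.columns)
        data = data.mask(mask)

    meta = pd.DataFrame({
        "mz": 100.0 + rng.random(p) * 900.0,
        "rt": 30.0 + rng.random(p) * 1200.0,
    }, index=var_ids)
    truth = {
        "informative_ids": [var_ids[i] for i in informative],
        "log_effects": dict(zip([var_ids[i] for i in informative], effects)),
    }
    return (PeakTable(data, meta), SampleMetadata(frame), truth)


def simulate_coupled_microbiome(
    metab: PeakTable,
    n_taxa: int = 20,
    n_linear: int = 2,
    n_nonlinear: int = 2,
    n_confounded: int = 0,
    confounder_strength: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[PeakTable, MicrobeTable, pd.DataFrame, SampleMetadata]:
    """Simulate a compositional taxa table coupled to a metabolite table.

    The first ``n_linear`` metabolites are linearly driven by the first
    ``n_linear`` taxa (on log scale); the next ``n_nonlinear`` metabolites
    depend quadratically on their taxon (zero linear correlation by
    symmetry); the next ``n_confounded`` metabolite-taxon pairs share a
    confounder but have no direct link.  The input table is not modified;
    returns (coupled metabolite table, microbe table, truth table,
    confounder metadata); truth lists each planted pair and its type.
    """
    if metab.n_samples < 20:
        raise ValueError("coupled simulation needs >= 20 samples")
    rng = np.random.default_rng(seed)
    n = metab.n_samples
    need = n_linear + n_nonlinear + n_confounded
    if need > n_taxa or need > metab.n_variables:
        raise ValueError("not enough taxa or metabolites for the planted pairs")

    log_taxa = rng.normal(0, 1, size=(n, n_taxa))
    confounder = rng.normal(0, 1, size=n)
    metab = metab.copy()
    data = metab.data
    truth_rows = []
    t = 0
    for i in range(n_linear):
        met = data.columns[i]
        taxon_signal = log_taxa[:, t]
        z = 2.0 * taxon_signal + rng.normal(0, noise_sd, size=n)
        data[met] = np.exp(np.log(data[met].mean()) + 0.3 * z)
        truth_rows.append({"metabolite": met, "taxon": f"T{t+1:03d}",
                           "type": "linear"})
        t += 1
    for i in range(n_nonlinear):
        met = data.columns[n_linear + i]
        taxon_signal = log_taxa[:, t]
        z = (taxon_signal - taxon_signal.mean()) ** 2
        z = (z - z.mean()) / max(z.std(), 1e-12)
        z = 2.0 * z + rng.normal(0, noise_sd, size=n)
        data[met] = np.exp(np.log(data[met].mean()) + 0.3 * z)
        truth_rows.append({"metabolite": met, "taxon": f"T{t+1:03d}",
                           "type": "nonlinear"})
        t += 1
    for i in range(n_confounded):
        met = data.columns[n_linear + n_nonlinear + i]
        log_taxa[:, t] += confounder_strength * confounder
        z = confounder_strength * confounder + rng.normal(0, noise_sd, size=n)
        data[met] = np.exp(np.log(data[met].mean()) + 0.3 * z)
        truth_rows.append({"metabolite": met, "taxon": f"T{t+1:03d}",
                           "type": "confounded"})
        t += 1

    abundances = np.exp(log_taxa)
    abundances = abundances / abundances.sum(axis=1, keepdims=True)
    taxa_ids = [f"T{j+1:03d}" for j in range(n_taxa)]
    microbe = MicrobeTable(pd.DataFrame(abundances, index=metab.sample_ids,
                                        columns=taxa_ids))
    conf_meta = SampleMetadata(pd.DataFrame(
        {"group": "all", "confounder": confounder},
        index=pd.Index(metab.sample_ids, name="sample_id")))
    return metab, microbe, pd.DataFrame(truth_rows), conf_meta


def simulate_pathway_library(
    n_pathways: int = 10,
    nodes_per_pathway: tuple[int, int] = (5, 15),
    species: str = "synth",
    reversible_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[PathwayLibrary, ReactionPairDB]:
    """Random connected pathway graphs plus the matching reaction-pair DB.

    Each pathway is a random spanning tree over its compounds with a few
    extra arcs; every edge appears as exactly one reaction pair, so ratio
    expansion and pathway analysis share a single ground truth.
    """
    rng = np.random.default_rng(seed)
    pathways, pairs = [], []
    compound_counter = 0
    for pw in range(n_pathways):
        n_nodes = int(rng.integers(nodes_per_pathway[0],
                                   nodes_per_pathway[1] + 1))
        nodes = [f"C{compound_counter + j + 1:04d}" for j in range(n_nodes)]
        compound_counter += n_nodes
        edges = []
        # random spanning tree (connected), directed parent -> child
        for j in range(1, n_nodes):
            parent = int(rng.integers(0, j))
            edges.append((nodes[parent], nodes[j],
                          bool(rng.random() < reversible_fraction)))
        n_extra = int(rng.integers(0, max(1, n_nodes // 3) + 1))
        for _ in range(n_extra):
            u, v = rng.choice(n_nodes, size=2, replace=False)
            edge = (nodes[int(u)], nodes[int(v)],
                    bool(rng.random() < reversible_fraction))
            if not any(e[0] == edge[0] and e[1] == edge[1] for e in edges):
                edges.append(edge)
        pid = f"path{pw+1:03d}"
        pathways.append(PathwayGraph(pid, f"Synthetic pathway {pw+1}",
                                     species, nodes, edges))
        for i, (u, v, rev) in enumerate(edges):
            pairs.append(ReactionPair(u, v, f"R_{pid}_{i+1:03d}",
                                      enzyme=f"EC.{pw+1}.{i+1}",
                                      reversible=rev))
    return PathwayLibrary(species, pathways), ReactionPairDB(pairs)


def simulate_compound_library(
    n_compounds: int = 50,
    with_spectra: bool = True,
    seed: int = 0,
) -> CompoundLibrary:
    """Random compound library with masses, RTs and centroided spectra."""
    rng = np.random.default_rng(seed)
    entries = []
    for i in range(n_compounds):
        mass = float(80.0 + rng.random() * 800.0)
        rt = float(30.0 + rng.random() * 1200.0)
        spectrum = None
        if with_spectra:
            n_peaks = int(rng.integers(5, 15))
            mzs = np.sort(rng.uniform(40, mass, size=n_peaks))
            intensities = rng.uniform(10, 999, size=n_peaks)
            spectrum = list(zip(mzs.tolist(), intensities.tolist()))
        entries.append(LibraryEntry(f"CPD{i+1:04d}", f"Compound {i+1}",
                                    mass, rt, spectrum))
    return CompoundLibrary(entries)
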