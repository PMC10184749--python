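"""End-to-end analyses over synthetic cohorts.

The four headline analyses — between-finger septa detection, inferior-to-
superior structural gradients, layer x finger ANOVAs, and finger-profile
similarity — plus the hand-versus-face body-part contrast, orchestrated
with explicit per-analysis bookkeeping of participants (per-pair n rather
than list-wise deletion, mirroring how missing crossings or peaks reduce
the sample for a single comparison only).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import geodesy, layers, mapping, similarity, stats, synthdata
from .core import (
    ANATOMICAL_LAYERS,
    FINGERS,
    NEIGHBOR_PAIRS,
    InvalidArgumentError,
    NoCrossingError,
    NoExtremaError,
)
from .synthdata import Cohort, Participant


@dataclass
class AnalysisConfig:
    """Reproducible run configuration: a run is a function of config + seed."""

    seed: int = 0
    n_participants: int = 20
    rows: int = 40
    cols: int = 60
    spacing: float = 0.26
    layer_scheme: str = "anatomical"
    topography: str = "ground_truth"      # or "fit" (pRF + GLM estimation)
    bold_noise_sd: float = 0.8
    septa_prior_scale: float = 0.707
    prf_confidence_threshold: float = 0.95
    corridor_n_paths: int = 5
    between_subject_sd: float = 0.26
    gradient_slope_qt1: float = 0.0
    septa: list = field(default_factory=list)
    with_face: bool = False
    out_dir: str = "results"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


def build_cohort(config: AnalysisConfig) -> Cohort:
    """Generate the cohort described by a config."""
    rows = config.rows if not config.with_face else max(config.rows, 90)
    mesh = synthdata.build_patch_mesh(rows, config.cols, config.spacing)
    truth = synthdata.default_truth(mesh, with_face=config.with_face,
                                    seed=config.seed,
                                    gradient_slope_qt1=config.gradient_slope_qt1)
    truth.septa = [synthdata.Septum(*s) if not isinstance(s, synthdata.Septum)
                   else s for s in config.septa]
    return synthdata.make_cohort(config.n_participants, truth,
                                 between_subject_sd=config.between_subject_sd,
                                 seed=config.seed, mesh=mesh)


# ---------------------------------------------------------------------------
# Shared preprocessing

def cohort_compartments(cohort: Cohort, scheme: str = "anatomical"):
    """Layer scheme from the group-level hand-ROI qT1 profile."""
    if scheme == "equally_spaced":
        return layers.define_equally_spaced_compartments()
    profs = []
    for p in cohort:
        roi = p.topography.hand_roi()
        profs.append(p.maps["qT1"][roi].mean(axis=0))
    group = np.mean(profs, axis=0)
    try:
        return layers.define_anatomical_compartments(group)
    except NoExtremaError:
        return layers.define_equally_spaced_compartments()


def participant_functional(p: Participant, config: AnalysisConfig,
                           rng: np.random.Generator) -> tuple:
    """Blocked-design GLM t-maps and a labelled topography for one participant.

    With ``config.topography == "fit"`` the topography is estimated from a
    simulated phase-encoded run via pRF fitting; otherwise the generative
    ground-truth topography is used (the fitting path is exercised by its
    own validation tests, and is much slower).
    """
    design = synthdata.generate_design(
        "blocked", seed=int(rng.integers(2 ** 31 - 1)))
    bold = synthdata.simulate_bold(p.topography, design,
                                   noise_sd=config.bold_noise_sd, rng=rng)
    glm = mapping.fit_glm_contrasts(bold, design)
    if config.topography == "fit":
        pe = synthdata.generate_design(
            "phase_encoded", seed=int(rng.integers(2 ** 31 - 1)))
        pe_bold = synthdata.simulate_bold(p.topography, pe,
                                          noise_sd=config.bold_noise_sd, rng=rng)
        topo = mapping.fit_prf(
            pe_bold, pe,
            confidence_threshold=config.prf_confidence_threshold)
    else:
        topo = p.topography
    labelled = mapping.assign_finger_rois(topo, glm)
    return glm, labelled


# ---------------------------------------------------------------------------
# Septa analysis

def run_septa_analysis(cohort: Cohort, config: AnalysisConfig | None = None,
                       comp=None) -> pd.DataFrame:
    """Peak-versus-border qT1 comparison for all neighboring finger pairs.

    For each participant: finger activation peaks (max t inside each pRF-
    restricted finger ROI), shortest peak-to-peak paths, t-value crossing
    borders, and layer-specific qT1 at the five peaks and four borders.
    Group level: one-sided JZS paired Bayes factors (H1: peak qT1 < border
    qT1, i.e. a low-myelin border) per pair x layer; participants without a
    valid crossing for a pair reduce that pair's n only.
    """
    config = config or AnalysisConfig()
    comp = comp if comp is not None else cohort_compartments(cohort, config.layer_scheme)
    labels = comp.labels
    rng = np.random.default_rng(config.seed + 1)
    samples: dict[tuple, dict[str, list]] = {
        (f"{a}-{b}", lay): {"peak": [], "border": []}
        for a, b in NEIGHBOR_PAIRS for lay in labels}
    for p in cohort:
        glm, topo = participant_functional(p, config, rng)
        lmaps = layers.compartment_average(p.maps["qT1"], comp)
        for a, b in NEIGHBOR_PAIRS:
            if a not in topo.peak_vertices or b not in topo.peak_vertices:
                continue
            pa, pb = topo.peak_vertices[a], topo.peak_vertices[b]
            try:
                path = geodesy.shortest_path(p.mesh, pa, pb, labels=(a, b))
                ta = glm.t_maps[a][path.vertex_chain]
                tb = glm.t_maps[b][path.vertex_chain]
                border = geodesy.find_border_crossing(ta, tb, path)
            except (NoCrossingError, InvalidArgumentError):
                continue
            for lay in labels:
                m = lmaps[lay]
                samples[(f"{a}-{b}", lay)]["peak"].append((m[pa] + m[pb]) / 2.0)
                samples[(f"{a}-{b}", lay)]["border"].append(m[border])
    rows = []
    for (pair, lay), d in samples.items():
        peak = np.asarray(d["peak"])
        border = np.asarray(d["border"])
        n = peak.size
        if n < 3:
            rows.append((lay, pair, np.nan, np.nan, np.nan, np.nan, n,
                         np.nan, np.nan))
            continue
        res = stats.jzs_paired_bf(border, peak, side="greater",
                                  prior_scale=config.septa_prior_scale)
        rows.append((lay, pair, peak.mean(), sps.sem(peak), border.mean(),
                     sps.sem(border), n, res.BF10, res.numerical_error))
    return pd.DataFrame(rows, columns=[
        "layer", "pair", "mean_peak", "sem_peak", "mean_border", "sem_border",
        "n", "BF10", "error"])


# ---------------------------------------------------------------------------
# Gradient analysis

_GRADIENT_CONTRASTS = ("qT1", "sQSM", "aQSM")


def _gradient_priors(contrast: str, layer: str):
    if contrast == "qT1":
        mean, sd = stats.QT1_LAYER_PRIORS.get(layer, (1800.0, 300.0))
        return (mean, sd), (0.0, sd)
    if contrast == "sQSM":
        return stats.QSM_SIGNED_PRIOR, stats.QSM_SIGNED_PRIOR
    return stats.QSM_ABS_PRIOR, (0.0, stats.QSM_ABS_PRIOR[1])


def gradient_start_finger(topo) -> str:
    """Most inferior of D1/D2; falls back to D2 when the order is reversed."""
    if "D1" not in topo.peak_vertices:
        return "D2"
    return "D1"


def collect_gradient_samples(cohort: Cohort, config: AnalysisConfig,
                             comp=None) -> tuple[pd.DataFrame, list[str]]:
    """Layer-specific values along each participant's D1(D2)-to-D5 path."""
    comp = comp if comp is not None else cohort_compartments(cohort, config.layer_scheme)
    rng = np.random.default_rng(config.seed + 2)
    tables, dropped = [], []
    for p in cohort:
        glm, topo = participant_functional(p, config, rng)
        start = gradient_start_finger(topo)
        if start == "D1" and "D2" in topo.peak_vertices:
            ya = p.mesh.surface_coords[topo.peak_vertices["D1"], 1]
            yb = p.mesh.surface_coords[topo.peak_vertices["D2"], 1]
            if ya > yb:   # reversed inferior-to-superior order
                start = "D2"
        if start not in topo.peak_vertices or "D5" not in topo.peak_vertices:
            dropped.append(p.label)
            continue
        path = geodesy.shortest_path(p.mesh, topo.peak_vertices[start],
                                     topo.peak_vertices["D5"],
                                     labels=(start, "D5"))
        maps = {"qT1": p.maps["qT1"],
                "sQSM": p.maps["nQSM"] + p.maps["pQSM"],
                "aQSM": p.maps["aQSM"]}
        for contrast, depth_map in maps.items():
            lmaps = layers.compartment_average(depth_map, comp)
            tab = geodesy.extract_gradient_samples(lmaps, path, p.label)
            tab.insert(0, "contrast", contrast)
            tables.append(tab)
    if not tables:
        raise InvalidArgumentError("no participant has a valid gradient path")
    return pd.concat(tables, ignore_index=True), dropped


def run_gradient_analysis(cohort: Cohort, config: AnalysisConfig | None = None,
                          comp=None, bayesian: bool = True,
                          contrasts=_GRADIENT_CONTRASTS) -> pd.DataFrame:
    """Frequentist and Bayesian multilevel gradient fits per layer x contrast."""
    config = config or AnalysisConfig()
    comp = comp if comp is not None else cohort_compartments(cohort, config.layer_scheme)
    samples, dropped = collect_gradient_samples(cohort, config, comp)
    n_layers = len(comp.labels)
    bonferroni = 0.05 / n_layers
    rows = []
    for contrast in contrasts:
        for layer in comp.labels:
            sub = samples[(samples.contrast == contrast) & (samples.layer == layer)]
            fit = stats.fit_mixed_model(sub.value.to_numpy(),
                                        sub.distance.to_numpy(),
                                        sub.participant.to_numpy(), layer=layer)
            row = {"contrast": contrast, "layer": layer, "beta": fit.slope,
                   "t": fit.t_stat, "p": fit.p_value, "ci_low": fit.ci95[0],
                   "ci_high": fit.ci95[1], "n": fit.n_participants,
                   "bonferroni_alpha": bonferroni,
                   "significant": fit.p_value < bonferroni,
                   "random_slope": fit.random_slope}
            if bayesian:
                ip, sp = _gradient_priors(contrast, layer)
                bfit = stats.bayes_mixed_model(
                    sub.value.to_numpy(), sub.distance.to_numpy(),
                    sub.participant.to_numpy(), intercept_prior=ip,
                    slope_prior=sp, seed=config.seed + 3, layer=layer)
                row.update({"beta_posterior": bfit.posterior_mean,
                            "cri_low": bfit.cri95[0], "cri_high": bfit.cri95[1],
                            "BF10": bfit.BF10, "rhat": bfit.rhat,
                            "n_draws": bfit.n_draws})
            rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["dropped"] = dropped
    return out


# ---------------------------------------------------------------------------
# Layer x finger structure

def finger_layer_table(cohort: Cohort, config: AnalysisConfig, comp,
                       contrast: str) -> np.ndarray:
    """(n, layers, fingers) mean values over each finger ROI."""
    vals = np.full((len(cohort), len(comp.labels), 5), np.nan)
    for i, p in enumerate(cohort):
        lmaps = layers.compartment_average(p.maps[contrast], comp)
        for li, lay in enumerate(comp.labels):
            for fi, f in enumerate(FINGERS):
                roi = p.topography.roi(f)
                if roi.size:
                    vals[i, li, fi] = lmaps[lay][roi].mean()
    return vals


def run_finger_structure_anova(cohort: Cohort, config: AnalysisConfig | None = None,
                               contrasts=("qT1", "nQSM", "pQSM", "aQSM"),
                               include_equally_spaced: bool = True,
                               include_outlier_excluded: bool = True) -> dict:
    """Two-way (layer x finger) repeated-measures ANOVAs per contrast."""
    config = config or AnalysisConfig()
    comp = cohort_compartments(cohort, config.layer_scheme)
    out: dict[str, dict] = {}
    for contrast in contrasts:
        tab = finger_layer_table(cohort, config, comp, contrast)
        keep = ~np.isnan(tab).any(axis=(1, 2))
        tab = tab[keep]
        entry = {"anova": stats.rm_anova_two_way(tab, factors=("layer", "finger")),
                 "n": int(tab.shape[0])}
        if include_outlier_excluded:
            flat = tab.reshape(tab.shape[0], -1)
            flagged = np.zeros(tab.shape[0], bool)
            for c in range(flat.shape[1]):
                flagged |= stats.extreme_outliers(flat[:, c])
            if flagged.any() and (~flagged).sum() >= 5:
                entry["anova_no_outliers"] = stats.rm_anova_two_way(
                    tab[~flagged], factors=("layer", "finger"))
                entry["n_no_outliers"] = int((~flagged).sum())
        if include_equally_spaced:
            comp4 = layers.define_equally_spaced_compartments()
            tab4 = finger_layer_table(cohort, config, comp4, contrast)
            tab4 = tab4[~np.isnan(tab4).any(axis=(1, 2))]
            entry["anova_equally_spaced"] = stats.rm_anova_two_way(
                tab4, factors=("layer", "finger"))
        out[contrast] = entry
    return out


# ---------------------------------------------------------------------------
# Similarity and meta-parameters

def finger_profiles(cohort: Cohort, contrast: str) -> dict[str, dict[str, np.ndarray]]:
    """participant -> finger -> mean 21-depth profile over the finger ROI."""
    out: dict[str, dict[str, np.ndarray]] = {}
    for p in cohort:
        profs = {}
        for f in FINGERS:
            roi = p.topography.roi(f)
            if roi.size:
                profs[f] = p.maps[contrast][roi].mean(axis=0)
        out[p.label] = profs
    return out


def one_way_rm_anova(data: np.ndarray, force_robust: bool = False):
    """One-way RM ANOVA; robust 20%-trimmed variant when non-normal."""
    data = np.asarray(data, float)
    normal = all(sps.shapiro(data[:, j]).pvalue >= 0.05
                 for j in range(data.shape[1]))
    trim = 0.0 if (normal and not force_robust) else 0.2
    res = stats.trimmed_rm_anova(data, trim=trim)
    res.effects["level"].correction = "trimmed" if trim else "none"
    return res, trim


def run_similarity_analysis(cohort: Cohort, config: AnalysisConfig | None = None,
                            contrasts=("qT1", "nQSM", "pQSM", "aQSM")) -> dict:
    """Fréchet matrices plus neighboring-pair and meta-parameter ANOVAs."""
    out: dict[str, dict] = {}
    for contrast in contrasts:
        profs = finger_profiles(cohort, contrast)
        individual, group, pairs, excluded = similarity.similarity_matrices(profs)
        pair_tab = pairs.pivot(index="participant", columns="pair",
                               values="distance")
        pair_tab = pair_tab[[f"{a}-{b}" for a, b in NEIGHBOR_PAIRS]].dropna()
        pair_anova = stats.trimmed_rm_anova(pair_tab.to_numpy(), trim=0.2)
        meta_rows = []
        meta_anovas = {}
        complete = [pid for pid, pr in profs.items()
                    if all(f in pr for f in FINGERS)]
        for param_idx, param in enumerate(("skewness", "kurtosis")):
            m = np.array([[stats.profile_meta(profs[pid][f])[param_idx]
                           for f in FINGERS] for pid in complete])
            res, trim = one_way_rm_anova(m)
            meta_anovas[param] = res
            for pid, row in zip(complete, m):
                for f, v in zip(FINGERS, row):
                    meta_rows.append((pid, f, param, v))
        out[contrast] = {
            "individual": individual, "group": group, "pairs": pairs,
            "pair_anova": pair_anova,
            "meta": pd.DataFrame(meta_rows, columns=["participant", "finger",
                                                     "parameter", "value"]),
            "meta_anovas": meta_anovas, "excluded": excluded,
            "n": len(individual)}
    return out


# ---------------------------------------------------------------------------
# Body-part contrast

def run_bodypart_contrast(cohort: Cohort, config: AnalysisConfig | None = None,
                          contrasts=("qT1", "nQSM", "pQSM", "aQSM")) -> dict:
    """Two-way (layer x body part) ANOVAs comparing hand and face regions."""
    config = config or AnalysisConfig()
    comp = cohort_compartments(cohort, config.layer_scheme)
    out = {}
    for contrast in contrasts:
        rows = []
        for p in cohort:
            if p.face_vertices is None or p.face_vertices.size == 0:
                continue
            lmaps = layers.compartment_average(p.maps[contrast], comp)
            hand = p.topography.hand_roi()
            cell = [[lmaps[lay][p.face_vertices].mean(),
                     lmaps[lay][hand].mean()] for lay in comp.labels]
            rows.append(cell)
        if not rows:
            out[contrast] = None
            continue
        tab = np.asarray(rows)      # (n, layers, 2)
        out[contrast] = {"anova": stats.rm_anova_two_way(
            tab, factors=("layer", "bodypart")), "n": tab.shape[0]}
    return out


# ---------------------------------------------------------------------------
# Corridor sampling (multidimensional septa detection)

def run_corridor_sampling(p: Participant, config: AnalysisConfig | None = None,
                          comp=None, axis: str = "y") -> pd.DataFrame:
    """Middle-depth qT1 along equally spaced face-to-D2 geodesic corridors."""
    config = config or AnalysisConfig()
    if p.truth.face_center_y is None:
        raise InvalidArgumentError("participant has no face subregion")
    if comp is None:
        try:
            comp = layers.define_anatomical_compartments(
                p.maps["qT1"][p.topography.hand_roi()].mean(axis=0))
        except NoExtremaError:
            comp = layers.define_equally_spaced_compartments()
    mid_label = "middle" if "middle" in comp.labels else comp.labels[1]
    mid = layers.compartment_average(p.maps["qT1"], comp)[mid_label]
    d1_roi = p.topography.roi("D1")
    if d1_roi.size == 0:
        raise InvalidArgumentError("no D1 representation")
    s = p.mesh.surface_coords
    x_mid = (s[:, 0].min() + s[:, 0].max()) / 2.0
    target = np.array([x_mid, p.truth.finger_band_centers[0]])
    seed_vertex = int(d1_roi[np.argmin(
        ((s[d1_roi] - target) ** 2).sum(axis=1))])
    paths = geodesy.corridor_paths(
        p.mesh, seed_vertex, inferior_y=p.truth.face_center_y,
        superior_y=p.truth.finger_band_centers[1],
        n_paths=config.corridor_n_paths, axis=axis)
    rows = []
    for k, path in enumerate(paths):
        dist, vals = geodesy.sample_along_path(mid, path)
        ys = p.mesh.surface_coords[path.vertex_chain, 1]
        for pos, (d, v, yy) in enumerate(zip(dist, vals, ys)):
            rows.append((k, pos, float(d), float(yy), float(v)))
    return pd.DataFrame(rows, columns=["path", "position", "distance_mm",
                                       "y_mm", "qT1"])


# ---------------------------------------------------------------------------
# Full run

def _anova_to_rows(name, contrast, res):
    rows = []
    for eff, e in res.effects.items():
        rows.append({"analysis": name, "contrast": contrast, "effect": eff,
                     "F": e.F, "df1": e.df[0], "df2": e.df[1], "p": e.p,
                     "eta_squared": e.eta_squared, "epsilon": e.epsilon,
                     "correction": e.correction})
    return rows


def run_all(config: AnalysisConfig, out_dir: str | None = None) -> dict:
    """Run every analysis on a freshly generated cohort; write CSV tables."""
    from pathlib import Path

    out_path = Path(out_dir or config.out_dir)
    out_path.mkdir(parents=True, exist_ok=True)
    cohort = build_cohort(config)
    comp = cohort_compartments(cohort, config.layer_scheme)

    septa = run_septa_analysis(cohort, config, comp)
    gradients = run_gradient_analysis(cohort, config, comp)
    anovas = run_finger_structure_anova(cohort, config)
    sim = run_similarity_analysis(cohort, config)
    results = {"septa": septa, "gradients": gradients, "anovas": anovas,
               "similarity": sim}
    septa.to_csv(out_path / "septa.csv", index=False)
    gradients.to_csv(out_path / "gradients.csv", index=False)
    anova_rows = []
    for contrast, entry in anovas.items():
        anova_rows += _anova_to_rows("layer_x_finger", contrast, entry["anova"])
        if "anova_equally_spaced" in entry:
            anova_rows += _anova_to_rows("layer_x_finger_equally_spaced",
                                         contrast, entry["anova_equally_spaced"])
    sim_rows = []
    for contrast, entry in sim.items():
        sim_rows += _anova_to_rows("similarity_pairs", contrast,
                                   entry["pair_anova"])
        entry["pairs"].assign(contrast=contrast).to_csv(
            out_path / f"similarity_pairs_{contrast}.csv", index=False)
    if config.with_face:
        bodypart = run_bodypart_contrast(cohort, config)
        results["bodypart"] = bodypart
        for contrast, entry in bodypart.items():
            if entry:
                anova_rows += _anova_to_rows("layer_x_bodypart", contrast,
                                             entry["anova"])
    pd.DataFrame(anova_rows + sim_rows).to_csv(out_path / "anovas.csv",
                                               index=False)
    manifest = {"config": asdict(config), "n_participants": len(cohort),
                "layer_scheme": comp.scheme,
                "compartment_sizes": list(comp.sizes())}
    (out_path / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                       default=str))
    results["manifest"] = manifest
    return results
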