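"""End-to-end decoding pipeline: head model -> inverse -> features -> CNN.

``build_head_model`` assembles the default desk-scale study fixture: a
three-shell concentric-sphere conduction model, a spherical-dome
cortical source space with radial fixed-orientation dipoles, the 14
standard 10-20 electrodes, the BEM lead field and the 18 virtual
electrodes.  ``decode_trials`` turns epoched scalp trials into the
(n, 640, 46, 9) tensor stack, and ``run_experiment`` executes the
5-fold 3:1:1 protocol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cnn import CNNClassifier, split_dataset
from .features import DEFAULT_FREQS, TensorScaler, morlet_power_multi
from .headmodel import (
    DEFAULT_CONDUCTIVITIES,
    BemSolver,
    LeadField,
    SourceSpace,
    lead_field,
    make_concentric_sphere_model,
    make_spherical_source_space,
    standard_electrode_positions,
)
from .inverse import InverseModel, choose_lambda, loreta_operator, solve_wmne
from .io import DEFAULT_CHANNELS, TrialSet
from .metrics import Metrics, evaluate
from .virtual import VirtualElectrode, define_virtual_pairs, extract_series

logger = logging.getLogger(__name__)


@dataclass
class HeadModelBundle:
    """Everything geometric the pipeline needs, built once."""

    solver: BemSolver
    source_space: SourceSpace
    electrodes: np.ndarray
    electrode_names: list[str]
    lead_field: LeadField
    ves: list[VirtualElectrode]


def make_dome_source_space(radius: float = 0.072,
                           subdivisions: int = 3) -> SourceSpace:
    """Spherical-dome template cortex: the superior half (z > 0) of an
    icosphere, where cortex lies relative to the electrode cap."""
    full = make_spherical_source_space(radius, subdivisions)
    keep = np.where(full.vertices[:, 2] > 1e-12)[0]
    remap = -np.ones(len(full.vertices), int)
    remap[keep] = np.arange(len(keep))
    tris = full.triangles[np.all(np.isin(full.triangles, keep), axis=1)]
    return SourceSpace(vertices=full.vertices[keep],
                       normals=full.normals[keep],
                       triangles=remap[tris])


def build_head_model(
    bem_subdivision: int = 2,
    source_subdivision: int = 3,
    radii: tuple[float, float, float] = (0.08, 0.085, 0.092),
    conductivities: tuple[float, ...] = DEFAULT_CONDUCTIVITIES,
    source_radius: float = 0.072,
    channels: list[str] | None = None,
) -> HeadModelBundle:
    """Build the default study fixture (spheres + dome cortex + 10-20)."""
    channels = list(channels or DEFAULT_CHANNELS)
    model = make_concentric_sphere_model(radii, conductivities,
                                         bem_subdivision)
    solver = BemSolver(model)
    src = make_dome_source_space(source_radius, source_subdivision)
    el = standard_electrode_positions(channels, radii[-1])
    lf = lead_field(solver, src, el, channels)
    ves = define_virtual_pairs(src)
    return HeadModelBundle(solver=solver, source_space=src, electrodes=el,
                           electrode_names=channels, lead_field=lf, ves=ves)


def make_inverse_operator(bundle: HeadModelBundle,
                          lam: float | str = "gcv",
                          sample_u: np.ndarray | None = None,
                          method: str = "loreta") -> np.ndarray:
    """Linear inverse operator T (n_sources x n_electrodes).

    ``lam='gcv'`` selects the Tikhonov weight by generalized
    cross-validation on ``sample_u`` (electrode x time data, e.g. a few
    trials); a float fixes it directly.
    """
    inv = InverseModel.from_lead_field(bundle.lead_field)
    if method == "wmne":
        # WMNE operator: lam ignored (lam = 0 formulation)
        n = bundle.lead_field.K.shape[0]
        return solve_wmne(inv, np.eye(n))
    if lam == "gcv":
        if sample_u is None:
            raise ValueError("lam='gcv' requires sample data")
        lam = choose_lambda(inv, sample_u)
        logger.info("GCV selected lambda = %.3e", lam)
    inv = InverseModel(K=inv.K, W=inv.W, L=inv.L, lam=float(lam))
    return loreta_operator(inv)


def virtual_series(trials_uv: np.ndarray, T: np.ndarray,
                   ves: list[VirtualElectrode]) -> np.ndarray:
    """Virtual-electrode time courses for a stack of scalp trials.

    ``trials_uv`` is (n_trials, n_channels, n_times) in microvolts;
    returns (n_trials, 18, n_times) in A*m.
    """
    trials_v = np.asarray(trials_uv, float) * 1e-6
    n_tr, _, n_t = trials_v.shape
    out = np.empty((n_tr, len(ves), n_t))
    for i, u in enumerate(trials_v):
        J = T @ u
        for j, ve in enumerate(ves):
            out[i, j] = extract_series(J, ve).values
    return out


def tensors_from_series(series: np.ndarray, fs: float,
                        ves: list[VirtualElectrode],
                        chunk: int = 64) -> np.ndarray:
    """Morlet power tensors (n, 640, 46, 9) from VE series (n, 18, T)."""
    pairs = sorted({v.pair for v in ves}, key=lambda p: int(p[1:]))
    li = {p: next(i for i, v in enumerate(ves)
                  if v.pair == p and v.hemisphere == "L") for p in pairs}
    ri = {p: next(i for i, v in enumerate(ves)
                  if v.pair == p and v.hemisphere == "R") for p in pairs}
    n, _, T = series.shape
    F = len(DEFAULT_FREQS)
    out = np.empty((n, T, 2 * F, len(pairs)), np.float32)
    for a in range(0, n, chunk):
        power = morlet_power_multi(series[a : a + chunk], fs)  # (c,18,F,T)
        for k, p in enumerate(pairs):
            out[a : a + chunk, :, :F, k] = \
                power[:, li[p]].transpose(0, 2, 1)
            out[a : a + chunk, :, F:, k] = \
                power[:, ri[p]].transpose(0, 2, 1)
    return out


def decode_trials(trials: TrialSet, bundle: HeadModelBundle,
                  lam: float | str = "gcv") -> np.ndarray:
    """Scalp trials -> joint time-frequency tensor stack."""
    sample = trials.trials[0] * 1e-6 if len(trials) else None
    T = make_inverse_operator(bundle, lam=lam, sample_u=sample)
    series = virtual_series(trials.trials, T, bundle.ves)
    return tensors_from_series(series, trials.fs, bundle.ves)


@dataclass
class FoldResult:
    metrics: Metrics
    classifier: CNNClassifier
    scaler: TensorScaler


def run_experiment(
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 5,
    folds_to_run: int | None = None,
    seed: int = 0,
    **cnn_params,
) -> list[FoldResult]:
    """The 3:1:1 five-part rotation protocol on a tensor stack.

    Normalisation statistics come from each fold's training split only.
    ``folds_to_run`` limits the rotation (e.g. 1 for a single fold).
    """
    folds = split_dataset(y, n_folds=n_folds, seed=seed)
    if folds_to_run is not None:
        folds = folds[:folds_to_run]
    results = []
    for f, (tr, va, te) in enumerate(folds):
        scaler = TensorScaler().fit(X[tr])
        clf = CNNClassifier(random_state=seed + f, **cnn_params)
        clf.fit(scaler.transform(X[tr]), y[tr],
                X_val=scaler.transform(X[va]), y_val=y[va])
        m = evaluate(clf, scaler.transform(X[te]), y[te])
        logger.info("fold %d: accuracy %.2f%%, kappa %.3f",
                    f, m.accuracy, m.kappa)
        results.append(FoldResult(metrics=m, classifier=clf, scaler=scaler))
    return results
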