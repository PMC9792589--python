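"""Preprocessing: impedance exclusion, ICA artifact removal, band filters.

Channels with 1 kHz impedance above 4 MΩ are flagged out (kept in the data
array so channel indexing is stable; every downstream operation skips
flagged channels).  Volume-conducted / globally coherent signal is removed
by blind source separation: the recording is decomposed into independent
components and components whose absolute mixing weights are near-uniform
across channels (coefficient of variation below a threshold) are
subtracted.  LFP (<250 Hz) and MUA (0.5-3 kHz) bands are extracted with
zero-phase (forward-backward) Chebyshev type II filters: flat passband,
>=40 dB stopband attenuation per pass, doubled by filtfilt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .data import Recording

__all__ = [
    "ICAReport",
    "exclude_channels",
    "remove_common_components",
    "filter_lfp",
    "filter_mua",
]


@dataclass
class ICAReport:
    """Summary of the common-component removal stage."""

    n_components: int
    removed_component_indices: List[int]
    mixing_uniformity: np.ndarray  # per-component CV of |mixing weight|
    variance_removed_fraction: float
    converged: bool = True
    #: near-uniform components retained because their time course is
    #: stimulus-locked (removal would delete evoked signal)
    protected_component_indices: List[int] = field(default_factory=list)


def exclude_channels(rec: Recording, max_impedance_ohm: float = 4e6) -> Recording:
    """Flag channels whose 1 kHz impedance exceeds ``max_impedance_ohm``.

    Data are retained; the ``included`` flag drives all downstream skips.
    Raises if nothing survives.
    """
    channels = [
        replace(c, included=c.included and c.impedance_ohm <= max_impedance_ohm)
        for c in rec.channels
    ]
    n_in = sum(c.included for c in channels)
    if n_in == 0:
        raise ValueError("all channels excluded by the impedance threshold")
    out = replace(rec, channels=channels)
    return out.with_data(
        rec.data, f"exclude_channels: max_impedance={max_impedance_ohm:g} Ω, {n_in} kept"
    )


def remove_common_components(
    rec: Recording,
    uniformity_cv_max: float = 0.25,
    seed: int = 0,
    ica_fs_hz: float = 250.0,
    removed_indices: Optional[Sequence[int]] = None,
    max_iter: int = 1000,
    strict_convergence: bool = True,
    fit_mask: Optional[np.ndarray] = None,
    protect_stimulus_locked: bool = True,
    protect_z_threshold: float = 8.0,
) -> Tuple[Recording, ICAReport]:
    """Remove independent components mixed near-uniformly across channels.

    The decomposition is estimated on data decimated to ``ica_fs_hz`` (the
    mixing is a static spatial transform, so it applies at any rate) and
    the removed components' contributions are subtracted from the
    broadband signal, leaving the MUA band intact.  A component is removed
    when the coefficient of variation of its absolute mixing weights across
    channels is <= ``uniformity_cv_max`` (volume-conducted signal and line
    noise project with near-identical weight everywhere).
    ``removed_indices`` overrides the automatic rule.

    ``fit_mask`` (boolean, one entry per broadband sample) restricts the
    samples the decomposition is *estimated* on — removal is still
    applied to the whole recording.  Fitting on stimulus-free segments
    keeps large evoked transients, which an instantaneous mixing model
    cannot represent cleanly, from leaking into the artifact components.

    With ``protect_stimulus_locked`` (default) and a stimulus present, a
    candidate component is retained when its trial-averaged time course
    around pulse onsets deviates from baseline by more than
    ``protect_z_threshold`` times the averaged-baseline noise — the
    automated equivalent of a curator declining to delete a component
    that carries the evoked response.  An instantaneous mixing model
    cannot fully separate propagating evoked waves from a uniformly
    mixed artifact, so an unprotected removal of the uniform direction
    subtracts the spatial-mean evoked wave and flattens latency maps.

    When the data contain a large Gaussian-noise subspace the iteration
    cannot converge there (rotations of Gaussian components are
    unidentifiable) even though the non-Gaussian common components are
    already isolated; ``strict_convergence=False`` proceeds in that case
    and flags ``converged=False`` in the report instead of raising.
    """
    idx = rec.included_indices()
    if idx.size < 4:
        raise ValueError("need at least 4 included channels for ICA")
    X = rec.data[idx]
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite samples in recording")

    q = max(1, int(round(rec.fs_hz / ica_fs_hz)))
    Xd = signal.resample_poly(X, up=1, down=q, axis=1) if q > 1 else X
    if fit_mask is not None:
        fit_mask = np.asarray(fit_mask, dtype=bool)
        if fit_mask.size != rec.n_samples:
            raise ValueError("fit_mask length must equal the number of samples")
        mask_d = fit_mask[np.minimum(np.arange(Xd.shape[1]) * q, fit_mask.size - 1)]
        if mask_d.sum() < 10 * idx.size:
            raise ValueError("fit_mask leaves too few samples to estimate the mixing")
        Xd = Xd[:, mask_d]

    cov = np.cov(Xd)
    if np.linalg.matrix_rank(cov, tol=1e-10 * np.trace(cov) / len(idx)) < idx.size:
        raise ValueError("rank-deficient data: channels are linearly dependent")

    ica = FastICA(
        n_components=idx.size, whiten="unit-variance", random_state=seed, max_iter=max_iter
    )
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            ica.fit(Xd.T)
        except ConvergenceWarning as e:
            if strict_convergence:
                raise RuntimeError(
                    f"ICA failed to converge after {max_iter} iterations: {e}"
                ) from e
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                ica.fit(Xd.T)

    A = ica.mixing_  # (n_channels, n_components)
    absA = np.abs(A)
    cv = absA.std(axis=0) / np.maximum(absA.mean(axis=0), np.finfo(float).tiny)

    if removed_indices is not None:
        removed = sorted(int(k) for k in removed_indices)
        protected: List[int] = []
    else:
        candidates = sorted(np.nonzero(cv <= uniformity_cv_max)[0].tolist())
        protected = []
        if protect_stimulus_locked and rec.stimulus is not None and candidates:
            S_cand = (X.T - ica.mean_) @ ica.components_[candidates].T  # (n_samp, n_cand)
            n_pre = int(0.1 * rec.fs_hz)
            n_post = int(0.3 * rec.fs_hz)
            for j, k in enumerate(candidates):
                epochs = []
                for onset in rec.stimulus.all_pulse_onsets_s():
                    i0 = int(round(onset * rec.fs_hz))
                    if i0 - n_pre >= 0 and i0 + n_post <= rec.n_samples:
                        epochs.append(S_cand[i0 - n_pre : i0 + n_post, j])
                if len(epochs) < 2:
                    continue
                avg = np.mean(epochs, axis=0)
                base = avg[:n_pre]
                noise = base.std()
                if noise == 0:
                    continue
                z = np.max(np.abs(avg[n_pre:] - base.mean())) / noise
                if z > protect_z_threshold:
                    protected.append(int(k))
        removed = [k for k in candidates if k not in protected]

    data = rec.data.copy()
    if removed:
        # project broadband data onto the estimated components and subtract
        # only the removed components' contribution
        S_rm = (X.T - ica.mean_) @ ica.components_[removed].T  # (n_samples, n_removed)
        data[idx] = X - (S_rm @ A[:, removed].T).T

    var_before = float(np.var(X))
    var_after = float(np.var(data[idx]))
    var_removed = 0.0 if var_before == 0 else float(np.clip(1 - var_after / var_before, 0, 1))

    report = ICAReport(
        n_components=int(idx.size),
        removed_component_indices=removed,
        mixing_uniformity=cv,
        variance_removed_fraction=var_removed,
        converged=converged,
        protected_component_indices=protected,
    )
    out = rec.with_data(
        data,
        f"remove_common_components: removed {removed} of {idx.size} components "
        f"(cv_max={uniformity_cv_max}, var_removed={var_removed:.3f}, "
        f"protected={protected})",
    )
    return out, report


# ---------------------------------------------------------------------------
# band extraction


def _lfp_sos(fs: float, cutoff_hz: float = 250.0, order: int = 8, rs_db: float = 40.0):
    if fs <= 2 * cutoff_hz:
        raise ValueError(f"sampling rate {fs} Hz too low for a {cutoff_hz} Hz low-pass")
    # type II: Wn is the stopband edge; put it at 1.2x the cutoff so the
    # passband stays flat through the band of interest
    return signal.cheby2(order, rs_db, 1.2 * cutoff_hz, btype="low", fs=fs, output="sos")


def _mua_sos(fs: float, band_hz: Tuple[float, float] = (500.0, 3000.0), order: int = 6,
             rs_db: float = 40.0):
    if fs < 8000:
        raise ValueError(f"sampling rate {fs} Hz cannot represent the 0.5-3 kHz MUA band")
    # stopband edges at half / double the band edges
    return signal.cheby2(order, rs_db, (band_hz[0] / 2, min(band_hz[1] * 2, 0.99 * fs / 2)),
                         btype="bandpass", fs=fs, output="sos")


def filter_lfp(rec: Recording, cutoff_hz: float = 250.0, order: int = 8) -> Recording:
    """Zero-phase low-pass below ``cutoff_hz`` (LFP band)."""
    sos = _lfp_sos(rec.fs_hz, cutoff_hz, order)
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.with_data(data, f"filter_lfp: <{cutoff_hz:g} Hz, Chebyshev II order {order}, zero-phase")


def filter_mua(rec: Recording, band_hz: Tuple[float, float] = (500.0, 3000.0),
               order: int = 6) -> Recording:
    """Zero-phase band-pass 0.5-3 kHz (MUA band)."""
    sos = _mua_sos(rec.fs_hz, band_hz, order)
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.with_data(
        data, f"filter_mua: {band_hz[0]:g}-{band_hz[1]:g} Hz, Chebyshev II order {order}, zero-phase"
    )
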