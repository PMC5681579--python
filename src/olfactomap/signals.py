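"""EAG trace containers and preprocessing.

Electroantennograms are extracellular field potentials summing odor-evoked
receptor-neuron currents; canonical responses are negative-going
deflections.  Preprocessing follows the standard recipe: Gaussian smoothing
(20 ms), subtraction of the paraffin-oil control response, and a signed
amplitude defined as the post-stimulus minimum minus the pre-stimulus mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "EAGRecording",
    "gaussian_smooth",
    "subtract_control",
    "response_amplitude",
    "absolute_response_amplitude",
    "normalize_panel",
    "preprocess",
]

#: Margin (s) required on both sides of the stimulus window.
_MARGIN_S = 0.5


@dataclass(frozen=True)
class EAGRecording:
    """Multi-position EAG traces for one odorant in one individual.

    Parameters
    ----------
    traces : ndarray, shape (n_samples, n_positions)
        Voltage in mV, one column per electrode position ordered
        proximal → distal.
    sampling_rate_hz : float
        Acquisition rate (500 Hz in the standard setup).
    stimulus_onset_s : float
        Odor-puff onset relative to the start of the trace.
    stimulus_duration_s : float
        Puff duration (0.2 s standard).
    control_traces : ndarray, optional
        Paraffin-oil control stimulations, same shape as ``traces``; a
        third axis may stack repeated controls (mean is used).
    """

    traces: np.ndarray
    sampling_rate_hz: float = 500.0
    stimulus_onset_s: float = 1.0
    stimulus_duration_s: float = 0.2
    control_traces: np.ndarray | None = None
    odorant: str = ""
    individual: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        tr = np.asarray(self.traces, dtype=float)
        if tr.ndim != 2:
            raise ValueError("traces must be 2-D (n_samples, n_positions)")
        if not np.all(np.isfinite(tr)):
            raise ValueError("traces contain NaN or infinite voltages")
        object.__setattr__(self, "traces", tr)
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        n, _ = tr.shape
        span = n / self.sampling_rate_hz
        if self.stimulus_onset_s - _MARGIN_S < 0 or (
            self.stimulus_onset_s + self.stimulus_duration_s + _MARGIN_S > span
        ):
            raise ValueError(
                f"stimulus window [{self.stimulus_onset_s}, "
                f"{self.stimulus_onset_s + self.stimulus_duration_s}] s needs a "
                f"{_MARGIN_S} s margin inside the recorded span of {span} s"
            )
        if self.control_traces is not None:
            ct = np.asarray(self.control_traces, dtype=float)
            if ct.shape[:2] != tr.shape:
                raise ValueError(
                    f"control_traces shape {ct.shape} does not match traces {tr.shape}"
                )
            if not np.all(np.isfinite(ct)):
                raise ValueError("control_traces contain NaN or infinite voltages")
            object.__setattr__(self, "control_traces", ct)

    @property
    def n_positions(self) -> int:
        return self.traces.shape[1]

    @property
    def n_samples(self) -> int:
        return self.traces.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz


def gaussian_smooth(
    trace: np.ndarray,
    width_s: float = 0.02,
    sampling_rate_hz: float = 500.0,
    axis: int = 0,
) -> np.ndarray:
    """Zero-phase Gaussian smoothing with a unit-area kernel.

    ``width_s`` is the kernel standard deviation (default 20 ms), truncated
    at ±4σ; edges are handled by reflect padding so the baseline windows are
    not contaminated by onset/offset ramps.
    """
    if width_s <= 0:
        raise ValueError(f"width_s must be positive, got {width_s}")
    trace = np.asarray(trace, dtype=float)
    sigma_samples = width_s * sampling_rate_hz
    support = 2 * int(4.0 * sigma_samples + 0.5) + 1
    if trace.shape[axis] <= support:
        raise ValueError(
            f"trace length {trace.shape[axis]} is not longer than the kernel "
            f"support of {support} samples"
        )
    return gaussian_filter1d(trace, sigma=sigma_samples, axis=axis, mode="reflect", truncate=4.0)


def subtract_control(trace: np.ndarray, control_trace: np.ndarray) -> np.ndarray:
    """Subtract the control (solvent-only) response, elementwise.

    If ``control_trace`` carries a trailing replicate axis (controls run
    before and after the odor sequence), the replicate mean is subtracted.
    """
    trace = np.asarray(trace, dtype=float)
    control = np.asarray(control_trace, dtype=float)
    if control.ndim == trace.ndim + 1:
        control = control.mean(axis=-1)
    if control.shape != trace.shape:
        raise ValueError(
            f"control shape {control.shape} does not match trace shape {trace.shape}"
        )
    return trace - control


def response_amplitude(
    trace: np.ndarray,
    onset_s: float,
    sampling_rate_hz: float = 500.0,
    window_s: float = 0.5,
) -> float:
    """Signed EAG amplitude: minimum over (onset, onset + 0.5 s] minus the
    mean over [onset − 0.5 s, onset).

    Negative for canonical odor-evoked deflections.  Invariant to adding a
    DC offset to the whole trace.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1:
        raise ValueError("response_amplitude expects a single 1-D trace")
    t = np.arange(trace.size) / sampling_rate_hz
    pre = (t >= onset_s - window_s) & (t < onset_s)
    post = (t > onset_s) & (t <= onset_s + window_s)
    if not pre.any() or t[0] > onset_s - window_s or t[-1] < onset_s + window_s:
        raise ValueError(
            f"trace does not cover [{onset_s - window_s}, {onset_s + window_s}] s"
        )
    return float(trace[post].min() - trace[pre].mean())


def absolute_response_amplitude(amplitudes) -> float:
    """Absolute response amplitude of the antenna: the maximum magnitude of
    the signed amplitudes over the recording positions.

    Using the max over positions avoids biasing single-position EAGs toward
    the selectivity of the nearest receptor neurons.
    """
    a = np.asarray(amplitudes, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one position amplitude")
    return float(np.abs(a).max())


def normalize_panel(amplitudes) -> np.ndarray:
    """Normalize per-odorant amplitudes by their sum so the panel sums to 1.

    Used before comparing response-amplitude patterns across individuals.
    """
    a = np.asarray(amplitudes, dtype=float)
    if a.size == 0:
        raise ValueError("empty odor panel")
    s = a.sum()
    if s <= 0:
        raise ValueError("panel sum must be positive to normalize (all-zero panel?)")
    return a / s


def preprocess(rec: EAGRecording, width_s: float = 0.02) -> EAGRecording:
    """Smooth all position traces and subtract the (mean) control.

    Returns a new recording; smoothing and control subtraction are linear
    and commute, so the order is immaterial.
    """
    traces = gaussian_smooth(rec.traces, width_s, rec.sampling_rate_hz, axis=0)
    if rec.control_traces is not None:
        control = rec.control_traces
        if control.ndim == 3:
            control = control.mean(axis=-1)
        control = gaussian_smooth(control, width_s, rec.sampling_rate_hz, axis=0)
        traces = traces - control
    return replace(rec, traces=traces, control_traces=None)
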