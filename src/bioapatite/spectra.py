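"""ATR FT-IR spectrum handling: loading, baseline correction, peak-height
ratio batteries and categorical heat/diagenesis markers.

The measurement conventions follow standard practice in burnt-bone
spectroscopy: absorbance peak heights are read as the window maximum within
a +/-5 cm^-1 tolerance of the nominal band position (the shift being
recorded), ratios are simple sums-of-heights quotients, and baselines are
piecewise-linear through local minima near a fixed anchor list
(450, 800, 900 and 1200 cm^-1 plus configurable extras for the
amide/cyanamide region).

The infrared splitting factor (IRSF) is the crystallinity index
(A565 + A605) / A_valley, the valley being the local minimum of the nu4
phosphate doublet; it rises with both heating and diagenetic
recrystallisation.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .errors import (
    AnchorError,
    ConfigurationError,
    EmptyInputError,
    FormatError,
    WindowError,
)

log = logging.getLogger(__name__)

#: default baseline anchors (cm^-1); the last three extend the published
#: four-anchor list into the carbonyl/cyanamide region.
DEFAULT_ANCHORS: tuple[float, ...] = (450.0, 800.0, 900.0, 1200.0, 1300.0, 1800.0, 2200.0)

#: half-width of the search window for the local minimum around an anchor.
ANCHOR_SEARCH_HALFWIDTH = 10.0

#: denominators at or below this absolute absorbance yield not-applicable.
DENOMINATOR_FLOOR = 1e-9


@dataclass(frozen=True)
class Spectrum:
    """A wavenumber-ordered absorbance trace with state metadata.

    Wavenumbers are stored ascending regardless of acquisition order.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    sample_id: str = ""
    state: str = "unknown"  # unburnt | burnt | unknown
    pmi_days: int | None = None

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wn.shape != ab.shape or wn.ndim != 1:
            raise FormatError("wavenumber and absorbance arrays must be equal-length 1-D")
        if wn.size and np.any(np.diff(wn) < 0):
            order = np.argsort(wn, kind="stable")
            wn, ab = wn[order], ab[order]
        if wn.size > 1 and np.any(np.diff(wn) <= 0):
            raise FormatError("wavenumbers must be strictly monotone after sorting")
        if np.any(~np.isfinite(ab)):
            raise FormatError("absorbance contains non-finite values")
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "absorbance", ab)

    def __len__(self) -> int:
        return self.wavenumbers.size

    def crop(self, lo: float, hi: float) -> "Spectrum":
        m = (self.wavenumbers >= lo) & (self.wavenumbers <= hi)
        return replace(self, wavenumbers=self.wavenumbers[m], absorbance=self.absorbance[m])


@dataclass(frozen=True)
class FeatureQuery:
    """Where and how to read one spectral feature."""

    center: float
    tolerance: float = 5.0
    mode: Literal["peak", "valley", "shoulder"] = "peak"

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ConfigurationError("feature tolerance must be >= 0")


@dataclass(frozen=True)
class FeatureMeasurement:
    height: float
    observed_center: float
    shift: float
    found: bool = True


@dataclass(frozen=True)
class RatioDefinition:
    name: str
    numerator: tuple[FeatureQuery, ...]
    denominator: tuple[FeatureQuery, ...]
    applicability: Literal["both", "unburnt-only", "burnt-only"] = "both"

    def __post_init__(self) -> None:
        if not self.denominator:
            raise ConfigurationError(f"ratio {self.name!r} has an empty denominator")

    def applies_to(self, state: str) -> bool:
        if self.applicability == "both":
            return True
        return self.applicability == f"{state}-only"


@dataclass
class MarkerReport:
    """Categorical heat/diagenesis markers read off one spectrum."""

    btcp_peak_1123: bool = False
    btcp_peak_height: float = 0.0
    shoulder_547: bool = False
    shoulder_547_strength: float = 0.0
    extra_peak_1080_1100: bool = False
    extra_peak_center: float | None = None
    oh_cl_peak: bool = False
    oh_cl_height: float = 0.0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class FtirRatioRecord:
    """The named ratio battery evaluated on one spectrum.

    Ratios excluded by the declared state (API and C/C are undefined for
    unburnt bone because the ~1540 cm^-1 type-A carbonate band overlaps
    amide II) carry ``nan`` and ``applicable=False``.
    """

    sample_id: str
    state: str
    pmi_days: int | None
    values: dict[str, float] = field(default_factory=dict)
    applicable: dict[str, bool] = field(default_factory=dict)
    shifts: dict[str, float] = field(default_factory=dict)
    markers: MarkerReport | None = None

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def to_row(self) -> dict:
        row: dict = {"sample_id": self.sample_id, "state": self.state, "pmi_days": self.pmi_days}
        for name, v in self.values.items():
            row[name] = v
            row[f"{name}_applicable"] = self.applicable[name]
        for key, shift in self.shifts.items():
            row[f"shift_{key}"] = shift
        if self.markers is not None:
            row.update(self.markers.to_dict())
        return row


# ---------------------------------------------------------------------------
# default ratio battery
# ---------------------------------------------------------------------------

def _q(center: float, tol: float = 5.0, mode: str = "peak") -> FeatureQuery:
    return FeatureQuery(center=center, tolerance=tol, mode=mode)  # type: ignore[arg-type]


def default_battery() -> list[RatioDefinition]:
    """Literature-standard band positions for the ten-ratio battery.

    Centers are defaults, not constants of nature; production runs should
    take them from the YAML configuration.
    """
    return [
        RatioDefinition("IRSF", (_q(565), _q(605)), (_q(587.5, 12.5, "valley"),)),
        RatioDefinition("C/P", (_q(1415),), (_q(1035),)),
        RatioDefinition("BPI", (_q(1415),), (_q(605),)),
        RatioDefinition("API", (_q(1540),), (_q(605),), "burnt-only"),
        RatioDefinition("C/C", (_q(1415),), (_q(1540),), "burnt-only"),
        RatioDefinition("CN/P", (_q(2010),), (_q(1035),)),
        RatioDefinition("CO/CO3", (_q(1740),), (_q(1415),)),
        RatioDefinition("N/P", (_q(1660),), (_q(1035),), "unburnt-only"),
        RatioDefinition("APR", (_q(1640),), (_q(1035),), "unburnt-only"),
        RatioDefinition("PHT", (_q(625),), (_q(610),)),
    ]


RATIO_NAMES: tuple[str, ...] = tuple(r.name for r in default_battery())


# ---------------------------------------------------------------------------
# io
# ---------------------------------------------------------------------------

def load_spectrum(source, fmt: Literal["csv", "jcamp"] = "csv") -> Spectrum:
    """Read a spectrum from two-column CSV or a minimal JCAMP-DX stream.

    CSV may carry ``# key: value`` comment headers (sample_id, state,
    pmi_days).  Duplicate wavenumbers are collapsed by averaging.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    elif isinstance(source, io.TextIOBase):
        text = source.read()
    else:
        text = str(source)
    if fmt == "csv":
        return _load_csv(text)
    if fmt == "jcamp":
        return _load_jcamp(text)
    raise ConfigurationError(f"unknown spectrum format {fmt!r}")


def _finalise(wn: list[float], ab: list[float], meta: dict) -> Spectrum:
    if not wn:
        raise EmptyInputError("spectrum input contains no data points")
    arr_wn = np.asarray(wn, dtype=float)
    arr_ab = np.asarray(ab, dtype=float)
    order = np.argsort(arr_wn, kind="stable")
    arr_wn, arr_ab = arr_wn[order], arr_ab[order]
    uniq, inverse, counts = np.unique(arr_wn, return_inverse=True, return_counts=True)
    if uniq.size != arr_wn.size:
        summed = np.zeros_like(uniq)
        np.add.at(summed, inverse, arr_ab)
        arr_wn, arr_ab = uniq, summed / counts
    pmi = meta.get("pmi_days")
    return Spectrum(
        arr_wn,
        arr_ab,
        sample_id=str(meta.get("sample_id", "")),
        state=str(meta.get("state", "unknown")),
        pmi_days=int(pmi) if pmi not in (None, "") else None,
    )


def _load_csv(text: str) -> Spectrum:
    wn: list[float] = []
    ab: list[float] = []
    meta: dict = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
            continue
        parts = [p for p in line.replace("\t", ",").split(",") if p.strip()]
        if len(parts) < 2:
            raise FormatError(f"line {lineno}: expected two columns, got {line!r}")
        try:
            x, y = float(parts[0]), float(parts[1])
        except ValueError:
            if lineno == 1 or (not wn and any(c.isalpha() for c in line)):
                continue  # header row
            raise FormatError(f"line {lineno}: unparseable numeric data {line!r}") from None
        wn.append(x)
        ab.append(y)
    return _finalise(wn, ab, meta)


def _load_jcamp(text: str) -> Spectrum:
    wn: list[float] = []
    ab: list[float] = []
    meta: dict = {}
    in_data = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = key.strip().upper()
            val = val.strip()
            if key == "XYDATA":
                in_data = True
            elif key == "END":
                in_data = False
            elif key == "TITLE":
                meta["sample_id"] = val
            elif key == "$STATE":
                meta["state"] = val
            elif key == "$PMIDAYS":
                meta["pmi_days"] = val
            continue
        if in_data:
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise FormatError(f"line {lineno}: bad XYDATA pair {line!r}")
            try:
                wn.append(float(parts[0]))
                ab.append(float(parts[1]))
            except ValueError:
                raise FormatError(f"line {lineno}: bad XYDATA pair {line!r}") from None
    return _finalise(wn, ab, meta)


def write_spectrum_csv(spectrum: Spectrum, path, descending: bool = True) -> None:
    """Write ``wavenumber_cm-1,absorbance`` with ``#`` metadata headers."""
    wn, ab = spectrum.wavenumbers, spectrum.absorbance
    if descending:
        wn, ab = wn[::-1], ab[::-1]
    lines = [
        f"# sample_id: {spectrum.sample_id}",
        f"# state: {spectrum.state}",
        f"# pmi_days: {'' if spectrum.pmi_days is None else spectrum.pmi_days}",
        "wavenumber_cm-1,absorbance",
    ]
    lines += [f"{x:.6f},{y:.10g}" for x, y in zip(wn, ab)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_spectrum_jcamp(spectrum: Spectrum, path) -> None:
    wn, ab = spectrum.wavenumbers[::-1], spectrum.absorbance[::-1]
    lines = [
        f"##TITLE={spectrum.sample_id}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=INFRARED SPECTRUM",
        "##XUNITS=1/CM",
        "##YUNITS=ABSORBANCE",
        f"##$STATE={spectrum.state}",
        f"##$PMIDAYS={'' if spectrum.pmi_days is None else spectrum.pmi_days}",
        f"##NPOINTS={len(spectrum)}",
        "##XYDATA=(XY..XY)",
    ]
    lines += [f"{x:.6f}, {y:.10g}" for x, y in zip(wn, ab)]
    lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# baseline correction
# ---------------------------------------------------------------------------

def baseline_correct(
    spectrum: Spectrum,
    anchors: Sequence[float] = DEFAULT_ANCHORS,
    search_halfwidth: float = ANCHOR_SEARCH_HALFWIDTH,
) -> Spectrum:
    """Subtract a piecewise-linear baseline through anchor-local minima.

    For each anchor the local minimum of absorbance within
    ``+/- search_halfwidth`` is taken as a baseline node; the interpolant
    through the nodes is subtracted and negative residuals are clipped at
    zero.  Beyond the outermost nodes the nearest segment is extended.
    The input spectrum is not modified.
    """
    wn, ab = spectrum.wavenumbers, spectrum.absorbance
    if len(anchors) < 2:
        raise AnchorError("need at least 2 baseline anchors")
    nodes_x: list[float] = []
    nodes_y: list[float] = []
    for a in sorted(anchors):
        m = (wn >= a - search_halfwidth) & (wn <= a + search_halfwidth)
        if not np.any(m):
            raise AnchorError(f"anchor {a} cm^-1 outside spectrum range "
                              f"[{wn[0]:.1f}, {wn[-1]:.1f}]")
        idx = np.flatnonzero(m)
        k = idx[np.argmin(ab[idx])]
        nodes_x.append(float(wn[k]))
        nodes_y.append(float(ab[k]))
    nx = np.asarray(nodes_x)
    ny = np.asarray(nodes_y)
    baseline = _piecewise_linear_extrapolated(wn, nx, ny)
    corrected = np.clip(ab - baseline, 0.0, None)
    return replace(spectrum, absorbance=corrected)


def _piecewise_linear_extrapolated(x: np.ndarray, nx: np.ndarray, ny: np.ndarray) -> np.ndarray:
    y = np.interp(x, nx, ny)
    # np.interp holds end values flat; extend the terminal segments linearly
    if nx.size >= 2:
        left = x < nx[0]
        if np.any(left):
            s = (ny[1] - ny[0]) / (nx[1] - nx[0])
            y[left] = ny[0] + s * (x[left] - nx[0])
        right = x > nx[-1]
        if np.any(right):
            s = (ny[-1] - ny[-2]) / (nx[-1] - nx[-2])
            y[right] = ny[-1] + s * (x[right] - nx[-1])
    return y


# ---------------------------------------------------------------------------
# feature measurement
# ---------------------------------------------------------------------------

def feature_height(
    spectrum: Spectrum,
    query: FeatureQuery,
    smooth_window: int = 11,
    smooth_order: int = 3,
) -> FeatureMeasurement:
    """Window max (peak), window min (valley) or second-derivative shoulder.

    Peaks follow the +/- tolerance shift rule: the maximum absorbance inside
    ``[center - tol, center + tol]`` is recorded along with the observed
    position; the shift is ``observed - nominal``.
    """
    wn, ab = spectrum.wavenumbers, spectrum.absorbance
    lo, hi = query.center - query.tolerance, query.center + query.tolerance
    if lo < wn[0] or hi > wn[-1]:
        raise WindowError(
            f"query window [{lo:.1f}, {hi:.1f}] outside spectrum range "
            f"[{wn[0]:.1f}, {wn[-1]:.1f}]"
        )
    m = (wn >= lo) & (wn <= hi)
    idx = np.flatnonzero(m)
    if idx.size == 0:
        raise WindowError(f"no grid points inside window [{lo:.1f}, {hi:.1f}]")
    if query.mode == "peak":
        k = idx[np.argmax(ab[idx])]
        return FeatureMeasurement(float(ab[k]), float(wn[k]), float(wn[k] - query.center))
    if query.mode == "valley":
        k = idx[np.argmin(ab[idx])]
        return FeatureMeasurement(float(ab[k]), float(wn[k]), float(wn[k] - query.center))
    # shoulder: local minimum of the smoothed second derivative (negative
    # curvature) inside the window, with no full local absorbance maximum.
    win = min(smooth_window, ab.size if ab.size % 2 == 1 else ab.size - 1)
    if win <= smooth_order:
        d2 = np.gradient(np.gradient(ab, wn), wn)
    else:
        dx = float(np.median(np.diff(wn)))
        d2 = savgol_filter(ab, win, smooth_order, deriv=2, delta=dx)
    has_local_max = False
    for k in idx:
        if 0 < k < ab.size - 1 and ab[k] > ab[k - 1] and ab[k] > ab[k + 1]:
            has_local_max = True
            break
    k = idx[np.argmin(d2[idx])]
    curv = float(d2[k])
    is_curv_min = 0 < k < ab.size - 1 and d2[k] <= d2[k - 1] and d2[k] <= d2[k + 1]
    found = curv < 0 and is_curv_min and not has_local_max
    return FeatureMeasurement(float(ab[k]), float(wn[k]), float(wn[k] - query.center), found)


def _sum_heights(
    spectrum: Spectrum, queries: Iterable[FeatureQuery], shifts: dict[str, float], prefix: str
) -> float:
    total = 0.0
    for i, q in enumerate(queries):
        meas = feature_height(spectrum, q)
        total += meas.height
        shifts[f"{prefix}_{q.center:g}"] = meas.shift
    return total


def compute_ratios(
    spectrum: Spectrum,
    battery: Sequence[RatioDefinition] | None = None,
    state: str | None = None,
) -> FtirRatioRecord:
    """Evaluate the peak-height ratio battery on a baseline-corrected spectrum.

    Inapplicable ratios (state-excluded) and zero-denominator ratios are
    nan-valued with ``applicable=False``; a zero denominator logs a warning
    rather than raising.
    """
    if battery is None:
        battery = default_battery()
    names = [r.name for r in battery]
    if len(set(names)) != len(names):
        raise ConfigurationError("ratio names must be unique in a battery")
    state = state if state is not None else spectrum.state
    record = FtirRatioRecord(spectrum.sample_id, state, spectrum.pmi_days)
    for rd in battery:
        if not rd.applies_to(state):
            record.values[rd.name] = math.nan
            record.applicable[rd.name] = False
            continue
        num = _sum_heights(spectrum, rd.numerator, record.shifts, f"{rd.name}_num")
        den = _sum_heights(spectrum, rd.denominator, record.shifts, f"{rd.name}_den")
        if den <= DENOMINATOR_FLOOR:
            log.warning("ratio %s: denominator ~0 (%.3g); marked not-applicable", rd.name, den)
            record.values[rd.name] = math.nan
            record.applicable[rd.name] = False
        else:
            record.values[rd.name] = num / den
            record.applicable[rd.name] = True
    return record


# ---------------------------------------------------------------------------
# marker detection
# ---------------------------------------------------------------------------

def _window_local_peak(
    spectrum: Spectrum, lo: float, hi: float, prominence: float
) -> tuple[bool, float, float]:
    """Strict local maximum inside [lo, hi] with the given prominence."""
    wn, ab = spectrum.wavenumbers, spectrum.absorbance
    pad = 25.0  # context so prominence is judged against neighbouring structure
    m = (wn >= lo - pad) & (wn <= hi + pad)
    idx = np.flatnonzero(m)
    if idx.size < 3:
        return False, 0.0, math.nan
    peaks, props = find_peaks(ab[idx], prominence=prominence)
    for p in peaks:
        x = wn[idx[p]]
        if lo <= x <= hi:
            return True, float(ab[idx[p]]), float(x)
    return False, 0.0, math.nan


def detect_markers(
    spectrum: Spectrum,
    btcp_center: float = 1123.0,
    btcp_tol: float = 5.0,
    shoulder_center: float = 547.0,
    shoulder_tol: float = 5.0,
    extra_band: tuple[float, float] = (1080.0, 1100.0),
    oh_cl_center: float = 3494.0,
    oh_cl_tol: float = 10.0,
    prominence_floor: float = 0.005,
) -> MarkerReport:
    """Detect beta-TCP (1123 peak + 547 shoulder), the burnt-bone
    1080-1100 cm^-1 extra peak and the OH-Cl high-temperature peak.

    All centers/thresholds are configurable; absence is a valid result.
    The OH-Cl position is a literature default, not a measured constant.
    """
    report = MarkerReport()
    present, height, _ = _window_local_peak(
        spectrum, btcp_center - btcp_tol, btcp_center + btcp_tol, prominence_floor
    )
    report.btcp_peak_1123 = present
    report.btcp_peak_height = height

    sh = feature_height(spectrum, FeatureQuery(shoulder_center, shoulder_tol, "shoulder"))
    report.shoulder_547 = sh.found
    report.shoulder_547_strength = sh.height if sh.found else 0.0

    present, _, center = _window_local_peak(
        spectrum, extra_band[0], extra_band[1], prominence_floor
    )
    report.extra_peak_1080_1100 = present
    report.extra_peak_center = center if present else None

    if oh_cl_center + oh_cl_tol <= spectrum.wavenumbers[-1]:
        present, height, _ = _window_local_peak(
            spectrum, oh_cl_center - oh_cl_tol, oh_cl_center + oh_cl_tol, prominence_floor
        )
        report.oh_cl_peak = present
        report.oh_cl_height = height
    return report
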