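"""Intrinsic DNA curvature from sequence and periodicity analysis of the result.

The model is the classical dinucleotide *wedge* model: every base-pair step
deflects the local helix axis by a small fixed roll/tilt wedge while the helix
twists by ~34.3 degrees per step.  Isolated wedges cancel over one helical turn,
but bends repeated *in phase* with the helical screw (A-tracts every ~10 bp)
add up coherently and produce macroscopic curvature — the property satellite
monomers with phased A-tracts exploit.

Curvature is measured on the reconstructed 3D helical path in a 40-bp sliding
window and expressed in degrees per helical turn.  Periodicity of curvature
tracks (and of A/T-tract indicator tracks) is analyzed with a fixed-length
DFT so that frequency bin ``k`` corresponds to a period of ``fs/k`` bp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WEDGE_TABLE",
    "TractTrack",
    "HelicalPath",
    "CurvatureProfile",
    "Spectrum",
    "find_tracts",
    "helical_path",
    "curvature_profile",
    "dft_spectrum",
    "period_to_bin",
    "bin_to_period",
    "tract_phase_shift",
    "export_path",
    "read_path",
]

# Per-dinucleotide (twist, wedge magnitude, wedge direction), all degrees.
# Trifonov-school wedge set: large AA/TT wedges, near-straight G/C steps.
# Complementary steps carry mirrored directions so that curvature of a
# reverse-complemented sequence reproduces the reversed profile.
WEDGE_TABLE: dict[str, tuple[float, float, float]] = {
    "AA": (34.5, 7.2, -154.0),
    "AC": (34.4, 1.1, 143.0),
    "AG": (34.7, 8.4, 2.0),
    "AT": (34.3, 2.6, 0.0),
    "CA": (34.1, 3.5, -64.0),
    "CC": (33.7, 2.1, -57.0),
    "CG": (29.8, 6.7, 0.0),
    "CT": (34.7, 8.4, -2.0),
    "GA": (36.9, 5.3, 120.0),
    "GC": (40.0, 5.0, 180.0),
    "GG": (33.7, 2.1, 57.0),
    "GT": (34.4, 1.1, -143.0),
    "TA": (36.0, 0.9, 0.0),
    "TC": (36.9, 5.3, -120.0),
    "TG": (34.1, 3.5, 64.0),
    "TT": (34.5, 7.2, 154.0),
}

BP_PER_TURN = 10  # integer helical period used for window statistics


@dataclass
class TractTrack:
    """Maximal A-runs and T-runs of length > 3 (``n > 3`` rule, N breaks runs)."""

    a_tracts: list[tuple[int, int]]
    t_tracts: list[tuple[int, int]]


@dataclass
class HelicalPath:
    """3D helix-axis path, one point per bp, unit rise between points."""

    points: np.ndarray  # (L, 3)
    seq_id: str = ""

    def __len__(self) -> int:
        return len(self.points)

    @property
    def tangents(self) -> np.ndarray:
        """Unit step vectors between consecutive points, shape (L-1, 3)."""
        d = np.diff(self.points, axis=0)
        return d / np.linalg.norm(d, axis=1, keepdims=True)

    def end_to_end_ratio(self) -> float:
        """End-to-end distance over contour length; 1.0 for a straight path."""
        e2e = float(np.linalg.norm(self.points[-1] - self.points[0]))
        contour = float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))
        return e2e / contour


@dataclass
class CurvatureProfile:
    values: np.ndarray  # degrees per helical turn, one per window center
    window: int = 40
    step: int = 1
    seq_id: str = ""


@dataclass
class Spectrum:
    power: np.ndarray  # length fs//2 + 1
    phase: np.ndarray  # degrees in (-180, 180], first segment
    fs: int = 1024
    n_segments: int = 1
    freq_bins: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.freq_bins is None:
            self.freq_bins = np.arange(self.fs // 2 + 1)


def _clean(seq: str) -> str:
    s = seq.upper().replace("U", "T")
    return s


def find_tracts(seq: str) -> TractTrack:
    """Locate A-tracts and T-tracts: maximal single-base runs of length >= 4.

    Runs of exactly 3 do not qualify (the n > 3 rule); any non-A (non-T)
    character, including N, terminates a run.
    """
    s = _clean(seq)

    def runs(base: str) -> list[tuple[int, int]]:
        out = []
        i = 0
        n = len(s)
        while i < n:
            if s[i] == base:
                j = i
                while j < n and s[j] == base:
                    j += 1
                if j - i >= 4:
                    out.append((i, j))
                i = j
            else:
                i += 1
        return out

    return TractTrack(a_tracts=runs("A"), t_tracts=runs("T"))


def _rot_x(deg: float) -> np.ndarray:
    r = math.radians(deg)
    c, s = math.cos(r), math.sin(r)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_z(deg: float) -> np.ndarray:
    r = math.radians(deg)
    c, s = math.cos(r), math.sin(r)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def helical_path(
    seq: str,
    twist_deg: float = 34.3,
    wedge_table: dict[str, tuple[float, float, float]] | None = None,
    seq_id: str = "",
) -> HelicalPath:
    """Build the predicted helix-axis path of a B-DNA duplex from sequence.

    Starting from the origin with the axis along +z, each dinucleotide step
    twists the local frame about the current axis and then deflects it by the
    step's wedge (roll/tilt decomposition of the wedge magnitude at the wedge
    direction).  The rise is one length unit per bp, so contour length equals
    sequence length − 1.

    Parameters
    ----------
    twist_deg:
        Helical twist applied per step when the wedge table does not supply
        a per-step twist (the default table does; this value is a fallback
        and is also used to derive the bp-per-turn used elsewhere).
    wedge_table:
        Mapping dinucleotide -> (twist, wedge, direction) in degrees.
        Swap in an alternative parameter set to change the model.
    """
    table = WEDGE_TABLE if wedge_table is None else wedge_table
    s = _clean(seq)
    if len(s) < 2:
        raise ValueError("sequence must be at least 2 bp")
    bad = set(s) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)}")

    points = np.zeros((len(s), 3))
    frame = np.eye(3)  # columns: local x, y, z(axis)
    pos = np.zeros(3)
    for i in range(len(s) - 1):
        step = s[i : i + 2]
        twist, wedge, direction = table.get(step, (twist_deg, 0.0, 0.0))
        # twist about the local axis, then deflect the axis by the wedge,
        # applied about an in-plane axis set by the wedge direction
        frame = frame @ _rot_z(twist)
        frame = frame @ _rot_z(direction) @ _rot_x(wedge) @ _rot_z(-direction)
        pos = pos + frame[:, 2]
        points[i + 1] = pos
    return HelicalPath(points=points, seq_id=seq_id)


def curvature_profile(
    path_or_seq: HelicalPath | str,
    window: int = 40,
    step: int = 1,
    **path_kwargs,
) -> CurvatureProfile:
    """Sliding-window curvature of a helical path, degrees per helical turn.

    Per window the mean helix-axis direction over the first helical turn is
    compared with the mean direction over the last turn; the angle between
    them, divided by the number of turns separating the two, is the window's
    curvature.  A straight helix scores ~0 regardless of twist because the
    wobble of individual step vectors averages out over a full turn.
    """
    if isinstance(path_or_seq, str):
        path = helical_path(path_or_seq, **path_kwargs)
    else:
        path = path_or_seq
    L = len(path)
    if L < window:
        raise ValueError(f"path length {L} shorter than window {window}")
    t = path.tangents  # (L-1, 3)
    turn = BP_PER_TURN
    # cumulative sums let every window reuse the same mean-direction arithmetic
    cs = np.vstack([np.zeros(3), np.cumsum(t, axis=0)])

    def mean_dir(a: int, b: int) -> np.ndarray:
        v = cs[b] - cs[a]
        return v / np.linalg.norm(v)

    n_windows = (L - window) // step + 1
    values = np.empty(n_windows)
    n_turns = (window - 1 - turn) / turn  # turn-center separation, in turns
    for w in range(n_windows):
        a = w * step
        d0 = mean_dir(a, a + turn)
        d1 = mean_dir(a + window - 1 - turn, a + window - 1)
        cosang = float(np.clip(np.dot(d0, d1), -1.0, 1.0))
        values[w] = math.degrees(math.acos(cosang)) / n_turns
    return CurvatureProfile(values=values, window=window, step=step, seq_id=path.seq_id)


def dft_spectrum(signal: np.ndarray, fs: int = 1024) -> Spectrum:
    """Fixed-length DFT power/phase spectrum of a real positional track.

    The track is cut into consecutive ``fs``-sample segments (the last one
    zero-padded); each segment is mean-centred and transformed; one-sided
    power is averaged over segments and satisfies Parseval's identity
    (sum of power = fs × segment variance) on full segments.  Phase is taken
    from the first segment, in degrees wrapped to (−180, 180].  Bin ``k``
    corresponds to a period of ``fs/k`` samples.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 2:
        raise ValueError("signal must have at least 2 samples")
    n_seg = max(1, math.ceil(x.size / fs))
    powers = []
    phase = None
    for i in range(n_seg):
        seg = x[i * fs : (i + 1) * fs]
        seg = seg - seg.mean()
        if seg.size < fs:
            seg = np.pad(seg, (0, fs - seg.size))
        X = np.fft.rfft(seg)
        p = np.abs(X) ** 2 / fs
        # fold the redundant negative-frequency half into one-sided power
        if fs % 2 == 0:
            p[1:-1] *= 2.0
        else:
            p[1:] *= 2.0
        powers.append(p)
        if phase is None:
            ph = np.degrees(np.angle(X))
            # wrap -180 to +180 so the range is (-180, 180]
            ph = np.where(ph <= -180.0, ph + 360.0, ph)
            phase = ph
    return Spectrum(
        power=np.mean(powers, axis=0), phase=phase, fs=fs, n_segments=n_seg
    )


def period_to_bin(period: float, fs: int = 1024) -> int:
    """Frequency-bin index of a given period: nearest integer of fs/period.

    Rounding is half-up, so bin = floor(fs/period + 0.5).
    """
    if period <= 0:
        raise ValueError("period must be positive")
    return int(math.floor(fs / period + 0.5))


def bin_to_period(bin_index: int, fs: int = 1024) -> float:
    """Exact period (in samples/bp) represented by a frequency bin."""
    if bin_index < 1:
        raise ValueError("bin index must be >= 1")
    return fs / bin_index


def _impulse_track(tracts: list[tuple[int, int]], length: int) -> np.ndarray:
    x = np.zeros(length)
    for s, e in tracts:
        center = (s + e - 1) / 2
        x[int(round(center))] = 1.0
    return x


def tract_phase_shift(
    track: TractTrack, fs: int = 1024, at_period: float = 20.0, length: int | None = None
) -> float:
    """Phase difference (degrees) between A- and T-tract alternation.

    Binary impulse trains are placed at tract centers; the phase of each
    train's DFT at the bin nearest ``fs/at_period`` is compared (A minus T),
    wrapped to (−180, 180].  Two tract families alternating at the same
    period but offset along the sequence show a shift proportional to the
    offset (360° × offset / period).
    """
    if not track.a_tracts or not track.t_tracts:
        raise ValueError("both A- and T-tract lists must be non-empty")
    if length is None:
        length = max(e for _, e in track.a_tracts + track.t_tracts)
    length = max(length, fs)
    a = _impulse_track(track.a_tracts, length)
    t = _impulse_track(track.t_tracts, length)
    k = period_to_bin(at_period, fs)
    Xa = np.fft.rfft(a[:fs])
    Xt = np.fft.rfft(t[:fs])
    d = math.degrees(np.angle(Xa[k]) - np.angle(Xt[k]))
    d = ((d + 180.0) % 360.0) - 180.0
    if d == -180.0:
        d = 180.0
    return d


def export_path(path: HelicalPath, out_path: str, scale: float = 3.38) -> None:
    """Write a helical path as a PDB-like pseudo-atom file, one CA per bp.

    ``scale`` converts the unit rise to Ångströms (3.38 Å/bp for B-DNA) so
    the file renders sensibly in molecular viewers.
    """
    if len(path) == 0:
        raise ValueError("empty path")
    with open(out_path, "w") as fh:
        fh.write(f"REMARK  helical path {path.seq_id or 'seq'}\n")
        for i, (x, y, z) in enumerate(path.points, start=1):
            fh.write(
                f"ATOM  {i % 100000:5d}  CA  DNA A{i % 10000:4d}    "
                f"{x * scale:8.3f}{y * scale:8.3f}{z * scale:8.3f}  1.00  0.00\n"
            )
        fh.write("END\n")


def read_path(in_path: str, scale: float = 3.38) -> HelicalPath:
    """Read back a pseudo-atom path written by :func:`export_path`."""
    pts = []
    with open(in_path) as fh:
        for line in fh:
            if line.startswith("ATOM"):
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                pts.append((x / scale, y / scale, z / scale))
    if not pts:
        raise ValueError("no ATOM records found")
    return HelicalPath(points=np.array(pts))
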