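"""Electrode geometry for the international 10-20/10-10 placement system.

Coordinates live on a unit-radius sphere modeling the head surface: +z points
through the vertex (Cz), +x through the nose, +y through the left preauricular
point. The layout is built analytically — midline and circumferential-ring
electrodes from their standard inclination/azimuth, intermediate electrodes by
interpolating along the circular arc joining their row's lateral anchor to the
midline — so homologous left/right pairs mirror exactly in the sagittal plane
and Cz sits exactly at the apex. Only relative geometry matters downstream:
spatial gating consumes inter-electrode distances, which are invariant to any
rigid rotation of the frame.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "Montage",
    "standard_montage",
    "pairwise_distance",
    "channel_distance_profile",
    "load_montage_json",
    "save_montage_json",
    "CHANNELS_32",
    "CHANNELS_22",
]

#: 32-electrode cap layout (extended 10-20), as on common 32-channel systems.
CHANNELS_32 = [
    "Fp1", "AF3", "F7", "F3", "FC1", "FC5", "T7", "C3",
    "CP1", "CP5", "P7", "P3", "Pz", "PO3", "O1", "Oz",
    "O2", "PO4", "P4", "P8", "CP6", "CP2", "C4", "T8",
    "FC6", "FC2", "F4", "F8", "AF4", "Fp2", "Fz", "Cz",
]

#: 22-electrode motor-imagery layout (central/centro-parietal 10-10 subset).
CHANNELS_22 = [
    "Fz", "FC3", "FC1", "FCz", "FC2", "FC4", "C5", "C3", "C1", "Cz", "C2",
    "C4", "C6", "CP3", "CP1", "CPz", "CP2", "CP4", "P1", "Pz", "P2", "POz",
]

_ALIASES = {"T3": "T7", "T4": "T8", "T5": "P7", "T6": "P8"}


def _sph(incl_deg: float, azim_deg: float) -> np.ndarray:
    """Unit vector at `incl_deg` from the vertex, azimuth from +x toward +y."""
    th = np.deg2rad(incl_deg)
    ph = np.deg2rad(azim_deg)
    return np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])


def _arc_point(left: np.ndarray, mid: np.ndarray, frac: float) -> np.ndarray:
    """Point at `frac` of the circular arc from `left` to `mid`.

    The arc lies on the circle through `left`, `mid` and the sagittal mirror
    of `left` — the sphere-surface path electrode rows follow on a cap.
    """
    right = left * np.array([1.0, -1.0, 1.0])
    n = np.cross(mid - left, right - left)
    n = n / np.linalg.norm(n)
    k = float(n @ left)
    center = k * n
    u = left - center
    r = np.linalg.norm(u)
    u = u / r
    v = np.cross(n, u)
    w = mid - center
    theta = np.arctan2(float(w @ v), float(w @ u))
    a = frac * theta
    p = center + r * (np.cos(a) * u + np.sin(a) * v)
    return p / np.linalg.norm(p)


def _mirror_name(name: str) -> str:
    """Left-hemisphere label -> homologous right-hemisphere label (odd -> +1)."""
    m = re.search(r"(\d+)$", name)
    assert m is not None
    return name[: m.start()] + str(int(m.group(1)) + 1)


def _build_table() -> dict[str, np.ndarray]:
    table: dict[str, np.ndarray] = {}
    # Midline: along the nasion-inion arc over the vertex, 18 deg steps.
    for name, incl, az in [
        ("Cz", 0, 0), ("FCz", 18, 0), ("Fz", 36, 0), ("AFz", 54, 0),
        ("Fpz", 72, 0), ("CPz", 18, 180), ("Pz", 36, 180), ("POz", 54, 180),
        ("Oz", 72, 180),
    ]:
        table[name] = _sph(incl, az)
    # Circumferential ring at 72 deg inclination, 18 deg azimuth steps
    # (left hemisphere; right comes from mirroring below).
    ring_left = [
        ("Fp1", 18), ("AF7", 36), ("F7", 54), ("FT7", 72), ("T7", 90),
        ("TP7", 108), ("P7", 126), ("PO7", 144), ("O1", 162),
    ]
    for name, az in ring_left:
        table[name] = _sph(72, az)
    # Intermediate rows: arc interpolation from the ring anchor to the midline.
    rows = [
        ("AF7", "AFz", {"AF3": 0.5}),
        ("F7", "Fz", {"F5": 0.25, "F3": 0.5, "F1": 0.75}),
        ("FT7", "FCz", {"FC5": 0.25, "FC3": 0.5, "FC1": 0.75}),
        ("T7", "Cz", {"C5": 0.25, "C3": 0.5, "C1": 0.75}),
        ("TP7", "CPz", {"CP5": 0.25, "CP3": 0.5, "CP1": 0.75}),
        ("P7", "Pz", {"P5": 0.25, "P3": 0.5, "P1": 0.75}),
        ("PO7", "POz", {"PO3": 0.5}),
    ]
    for anchor, mid, members in rows:
        for name, frac in members.items():
            table[name] = _arc_point(table[anchor], table[mid], frac)
    # Right hemisphere: exact sagittal mirror of every left electrode.
    for name in [n for n in table if re.search(r"[13579]$", n)]:
        table[_mirror_name(name)] = table[name] * np.array([1.0, -1.0, 1.0])
    return table


_TABLE = _build_table()


@dataclass(frozen=True)
class Montage:
    """Ordered channel labels with unit-sphere 3D coordinates.

    Channel order is significant: it must match the column order of every
    trial matrix used with the montage.
    """

    channel_names: tuple[str, ...]
    coords: np.ndarray  # (D, 3)

    def __post_init__(self) -> None:
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=np.float64))
        if self.coords.shape != (len(self.channel_names), 3):
            raise ValueError("coords must be (n_channels, 3)")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("duplicate channel names in montage")
        norms = np.linalg.norm(self.coords, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("montage coordinates must lie on the unit sphere")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        return self.channel_names.index(name)


def standard_montage(channel_names) -> Montage:
    """Build a montage from standard 10-20/10-10 labels.

    Legacy aliases (T3/T4/T5/T6) are accepted and resolved to their modern
    names while preserving the label the caller asked for.
    """
    coords = []
    for name in channel_names:
        key = _ALIASES.get(name, name)
        if key not in _TABLE:
            raise ValueError(f"unknown 10-20 channel label: {name!r}")
        coords.append(_TABLE[key])
    return Montage(tuple(channel_names), np.array(coords))


def montage_32() -> Montage:
    """Standard 32-channel fixture."""
    return standard_montage(CHANNELS_32)


def montage_22() -> Montage:
    """Standard 22-channel motor-imagery fixture."""
    return standard_montage(CHANNELS_22)


def pairwise_distance(montage) -> np.ndarray:
    """Symmetric Euclidean distance matrix between all electrode pairs.

    Accepts a :class:`Montage` or a plain ``(D, 3)`` coordinate array.
    """
    coords = montage.coords if isinstance(montage, Montage) else np.asarray(montage, float)
    if coords.ndim != 2 or coords.shape[0] == 0:
        raise ValueError("need a nonempty (D, 3) coordinate array")
    return squareform(pdist(coords))


def channel_distance_profile(distance_matrix: np.ndarray, d: int) -> np.ndarray:
    """Distances from channel ``d`` to every channel (row ``d`` of the matrix)."""
    distance_matrix = np.asarray(distance_matrix)
    if not 0 <= d < distance_matrix.shape[0]:
        raise IndexError(f"channel index {d} out of range")
    return distance_matrix[d]


def save_montage_json(montage: Montage, path) -> None:
    payload = {
        "channels": [
            {"name": n, "xyz": [float(c) for c in xyz]}
            for n, xyz in zip(montage.channel_names, montage.coords)
        ]
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def load_montage_json(path) -> Montage:
    """Read a ``{"channels": [{"name", "xyz"}]}`` montage file.

    Coordinates are validated to be near unit norm (1e-6, to tolerate decimal
    round-tripping) and renormalized exactly.
    """
    with open(path) as fh:
        payload = json.load(fh)
    names = [ch["name"] for ch in payload["channels"]]
    coords = np.array([ch["xyz"] for ch in payload["channels"]], dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("each channel needs a 3-vector 'xyz'")
    norms = np.linalg.norm(coords, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        bad = names[int(np.argmax(np.abs(norms - 1.0)))]
        raise ValueError(f"channel {bad!r} coordinate is not on the unit sphere")
    return Montage(tuple(names), coords / norms[:, None])
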