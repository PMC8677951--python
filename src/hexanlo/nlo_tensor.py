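"""Hyper-Rayleigh-scattering invariants of the first hyperpolarizability tensor.

The first hyperpolarizability β is a rank-3 tensor (27 real components, atomic
units) describing the quadratic response of the molecular dipole to an electric
field.  Hyper-Rayleigh scattering (HRS) measures incoherent second-harmonic
light from an isotropic ensemble; its intensity is governed by two rotational
invariants, the orientational averages ⟨β²_ZZZ⟩ and ⟨β²_ZXX⟩, through

    β_HRS = sqrt(⟨β²_ZZZ⟩ + ⟨β²_ZXX⟩)

with the depolarization ratio DR = ⟨β²_ZZZ⟩ / ⟨β²_ZXX⟩ (DR = 5 for a single
diagonal component, e.g. a one-dimensional push-pull chromophore).

The closed forms implemented here assume only the intrinsic second-harmonic
permutation symmetry β_ijk = β_ikj (no Kleinman symmetry).  A Monte-Carlo
rotational-averaging oracle over Haar-uniform rotations is provided as an
independent numerical check of the closed forms.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from itertools import permutations, product
from pathlib import Path

import numpy as np

__all__ = [
    "BetaTensor",
    "HRSResult",
    "symmetrize_shg",
    "orientational_averages",
    "beta_hrs",
    "rotate_tensor",
    "mc_rotational_average",
    "read_beta_tensor",
    "write_beta_tensor",
    "BetaTensorError",
]

logger = logging.getLogger(__name__)

_AXES = "xyz"
_SCHEMA = "hexanlo-beta-v1"


class BetaTensorError(ValueError):
    """Invalid β tensor input (non-finite components, bad file, bad rotation)."""


@dataclass(frozen=True)
class BetaTensor:
    """A 3×3×3 first-hyperpolarizability tensor in atomic units.

    Parameters
    ----------
    components : (3, 3, 3) array_like
        β_ijk with indices ordered x, y, z.
    frequency : float
        Photon energy of the incident light in eV; 0 means the static limit.
    """

    components: np.ndarray
    frequency: float = 0.0

    def __post_init__(self):
        arr = np.asarray(self.components, dtype=float)
        if arr.shape != (3, 3, 3):
            raise BetaTensorError(f"expected shape (3, 3, 3), got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise BetaTensorError("beta tensor has non-finite components")
        if not np.isfinite(self.frequency):
            raise BetaTensorError("frequency must be finite")
        object.__setattr__(self, "components", arr)

    def component(self, key: str) -> float:
        """Return β_ijk by axis string, e.g. ``t.component("zxx")``."""
        i, j, k = (_AXES.index(c) for c in key.lower())
        return float(self.components[i, j, k])

    @classmethod
    def from_dict(cls, entries: dict[str, float], frequency: float = 0.0,
                  sparse: bool = False) -> "BetaTensor":
        """Build from a mapping ``{"xxx": ..., ..., "zzz": ...}``.

        With ``sparse=True`` missing keys default to zero; otherwise all 27
        keys must be present.
        """
        valid = {a + b + c for a, b, c in product(_AXES, repeat=3)}
        arr = np.zeros((3, 3, 3))
        seen = set()
        for key, value in entries.items():
            k = key.lower()
            if k not in valid:
                raise BetaTensorError(f"unknown tensor component key {key!r}")
            try:
                v = float(value)
            except (TypeError, ValueError):
                raise BetaTensorError(
                    f"non-numeric value for component {key!r}: {value!r}"
                ) from None
            i, j, kk = (_AXES.index(c) for c in k)
            arr[i, j, kk] = v
            seen.add(k)
        if not sparse and seen != valid:
            missing = sorted(valid - seen)
            raise BetaTensorError(
                f"missing components {missing[:5]}{'...' if len(missing) > 5 else ''};"
                " pass sparse=True to default them to zero"
            )
        return cls(arr, frequency)


@dataclass(frozen=True)
class HRSResult:
    """HRS invariants: β_HRS, the two orientational averages, and DR."""

    beta_hrs: float
    avg_zzz2: float
    avg_zxx2: float
    depolarization_ratio: float = field(default=float("nan"))


def symmetrize_shg(t: BetaTensor) -> BetaTensor:
    """Enforce intrinsic SHG symmetry by averaging the last two indices."""
    b = t.components
    return BetaTensor(0.5 * (b + np.swapaxes(b, 1, 2)), t.frequency)


def _pair_sums(b: np.ndarray):
    """Sums over index patterns appearing in the non-Kleinman averages."""
    idx = range(3)
    s = dict.fromkeys(
        ["iii2", "iij2", "iii_ijj", "jii_iij", "iii_jji", "jii2",
         "ijj2", "iij_jii",
         "iij_jkk", "jii_jkk", "iij_kkj", "ijk2", "ijk_jik",
         "ijj_jkk", "iik_jjk"],
        0.0,
    )
    s["iii2"] = float(np.sum(np.array([b[i, i, i] for i in idx]) ** 2))
    for i, j in permutations(idx, 2):
        s["iij2"] += b[i, i, j] ** 2
        s["iii_ijj"] += b[i, i, i] * b[i, j, j]
        s["jii_iij"] += b[j, i, i] * b[i, i, j]
        s["iii_jji"] += b[i, i, i] * b[j, j, i]
        s["jii2"] += b[j, i, i] ** 2
        s["ijj2"] += b[i, j, j] ** 2
        s["iij_jii"] += b[i, i, j] * b[j, i, i]
    for i, j, k in permutations(idx, 3):
        s["iij_jkk"] += b[i, i, j] * b[j, k, k]
        s["jii_jkk"] += b[j, i, i] * b[j, k, k]
        s["iij_kkj"] += b[i, i, j] * b[k, k, j]
        s["ijk2"] += b[i, j, k] ** 2
        s["ijk_jik"] += b[i, j, k] * b[j, i, k]
        s["ijj_jkk"] += b[i, j, j] * b[j, k, k]
        s["iik_jjk"] += b[i, i, k] * b[j, j, k]
    return s


def orientational_averages(t: BetaTensor) -> tuple[float, float]:
    """Closed-form isotropic averages ⟨β²_ZZZ⟩ and ⟨β²_ZXX⟩.

    These are the standard second-harmonic orientational averages without
    Kleinman symmetry, i.e. assuming only β_ijk = β_ikj.  The tensor is not
    symmetrized here; apply :func:`symmetrize_shg` first if the input does not
    already satisfy the intrinsic symmetry.
    """
    s = _pair_sums(t.components)
    zzz2 = (
        s["iii2"] / 7
        + 4 * s["iij2"] / 35
        + 2 * s["iii_ijj"] / 35
        + 4 * s["jii_iij"] / 35
        + 4 * s["iii_jji"] / 35
        + s["jii2"] / 35
        + 4 * s["iij_jkk"] / 105
        + s["jii_jkk"] / 105
        + 4 * s["iij_kkj"] / 105
        + 2 * s["ijk2"] / 105
        + 4 * s["ijk_jik"] / 105
    )
    zxx2 = (
        s["iii2"] / 35
        + 4 * s["iii_ijj"] / 105
        - 2 * s["iii_jji"] / 35
        + 8 * s["iij2"] / 105
        + 3 * s["ijj2"] / 35
        - 2 * s["iij_jii"] / 35
        + s["jii_jkk"] / 35
        - 2 * s["iik_jjk"] / 105
        - 2 * s["iij_jkk"] / 105
        + 2 * s["ijk2"] / 35
        - 2 * s["ijk_jik"] / 105
    )
    return float(zzz2), float(zxx2)


def beta_hrs(t: BetaTensor) -> HRSResult:
    """β_HRS and depolarization ratio from the closed-form averages.

    A centrosymmetric structure has an identically zero β tensor and hence
    β_HRS = 0.
    """
    zzz2, zxx2 = orientational_averages(t)
    dr = zzz2 / zxx2 if zxx2 > 0 else float("nan")
    return HRSResult(
        beta_hrs=float(np.sqrt(zzz2 + zxx2)),
        avg_zzz2=zzz2,
        avg_zxx2=zxx2,
        depolarization_ratio=dr,
    )


def rotate_tensor(t: BetaTensor, R: np.ndarray, tol: float = 1e-8) -> BetaTensor:
    """Rotate the tensor: β'_ijk = Σ_abc R_ia R_jb R_kc β_abc.

    ``R`` must be a proper rotation (orthogonal, det +1) to within ``tol``.
    """
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise BetaTensorError("rotation matrix must be 3x3")
    if not np.allclose(R @ R.T, np.eye(3), atol=tol) or abs(np.linalg.det(R) - 1) > tol:
        raise BetaTensorError("matrix is not a proper rotation (orthogonal, det +1)")
    rotated = np.einsum("ia,jb,kc,abc->ijk", R, R, R, t.components)
    return BetaTensor(rotated, t.frequency)


def mc_rotational_average(
    t: BetaTensor, n_samples: int, seed: int, chunk: int = 200_000,
    return_se: bool = False,
):
    """Monte-Carlo estimate of ⟨β²_ZZZ⟩ and ⟨β²_ZXX⟩ over Haar-uniform rotations.

    Rotations are generated from unit quaternions drawn from the 4D standard
    normal (normalization makes them Haar-uniform on SO(3)).  For each sample
    the laboratory-frame components β'_ZZZ and β'_ZXX are contracted directly
    from the rotation rows, avoiding the full 27-component rotation.

    This is an oracle for :func:`orientational_averages`; the estimator
    converges to the closed forms as ``n_samples → ∞`` and is reproducible for
    a fixed seed.

    With ``return_se=True`` also returns the two standard errors of the mean,
    i.e. ``(avg_zzz2, avg_zxx2, se_zzz2, se_zxx2)``.
    """
    if n_samples < 1:
        raise BetaTensorError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    b = t.components
    tot = np.zeros(2)  # sums of squares
    tot_sq = np.zeros(2)  # sums of fourth powers, for the variance
    done = 0
    while done < n_samples:
        n = min(chunk, n_samples - done)
        q = rng.normal(size=(n, 4))
        q /= np.linalg.norm(q, axis=1, keepdims=True)
        w, x, y, z = q.T
        # rows of the rotation matrix: X = first row, Z = third row
        X = np.stack(
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            axis=1,
        )
        Z = np.stack(
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
            axis=1,
        )
        bzzz2 = np.einsum("na,nb,nc,abc->n", Z, Z, Z, b, optimize=True) ** 2
        bzxx2 = np.einsum("na,nb,nc,abc->n", Z, X, X, b, optimize=True) ** 2
        tot += [bzzz2.sum(), bzxx2.sum()]
        tot_sq += [np.sum(bzzz2**2), np.sum(bzxx2**2)]
        done += n
    mean = tot / n_samples
    if not return_se:
        return float(mean[0]), float(mean[1])
    var = np.maximum(tot_sq / n_samples - mean**2, 0.0)
    se = np.sqrt(var / n_samples)
    return float(mean[0]), float(mean[1]), float(se[0]), float(se[1])


def read_beta_tensor(path, symmetrize: bool = True) -> BetaTensor:
    """Read a β tensor from the ``hexanlo-beta-v1`` JSON dialect.

    Schema: ``{"schema": "hexanlo-beta-v1", "frequency_eV": 0.0,
    "sparse": false, "components": {"xxx": ..., ..., "zzz": ...}}``.
    A missing ``frequency_eV`` defaults to the static limit (0 eV) with a
    logged warning.  With ``"sparse": true`` absent components default to 0.
    By default the intrinsic SHG symmetry is enforced on read by averaging the
    last two indices; pass ``symmetrize=False`` to keep the raw components.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise BetaTensorError(f"malformed JSON in {path}: {exc}") from exc
    if not isinstance(doc, dict) or "components" not in doc:
        raise BetaTensorError(f"{path}: missing required key 'components'")
    schema = doc.get("schema", _SCHEMA)
    if schema != _SCHEMA:
        raise BetaTensorError(f"{path}: unsupported schema {schema!r}")
    if "frequency_eV" in doc:
        freq = float(doc["frequency_eV"])
    else:
        freq = 0.0
        logger.warning("%s: no 'frequency_eV' field; assuming static (0 eV)", path)
        warnings.warn(f"{path}: no 'frequency_eV' field; assuming static (0 eV)",
                      stacklevel=2)
    t = BetaTensor.from_dict(doc["components"], frequency=freq,
                             sparse=bool(doc.get("sparse", False)))
    return symmetrize_shg(t) if symmetrize else t


def write_beta_tensor(t: BetaTensor, path) -> None:
    """Write a tensor in the ``hexanlo-beta-v1`` JSON dialect (27 dense keys)."""
    comps = {
        a + bb + c: t.components[_AXES.index(a), _AXES.index(bb), _AXES.index(c)]
        for a, bb, c in product(_AXES, repeat=3)
    }
    doc = {"schema": _SCHEMA, "frequency_eV": t.frequency,
           "sparse": False, "components": comps}
    Path(path).write_text(json.dumps(doc, indent=1))
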