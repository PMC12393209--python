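"""Diffusion-encoding schemes: shell structure, direction sets, FSL-style I/O.

The cardiac DKI protocol modelled here uses five b-value shells
[100, 450, 900, 1200, 1350 s/mm**2] with 30 directions x 6 repeats per shell,
except the lowest shell which has 3 directions x 12 repeats.  No b=0 image is
acquired; S0 is always a fitted parameter downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "AcquisitionScheme",
    "electrostatic_directions",
    "build_protocol",
    "write_gradient_table",
    "read_gradient_table",
    "GradientTableError",
]

#: The in-vivo protocol's shells, s/mm^2.
PROTOCOL_BVALS = (100.0, 450.0, 900.0, 1200.0, 1350.0)


class GradientTableError(ValueError):
    """Malformed or inconsistent bval/bvec files."""


@dataclass(frozen=True)
class AcquisitionScheme:
    """One row per measurement: b-value, unit encoding direction, shell, repeat.

    Invariants: ``bvals >= 0``; every ``bvec`` has unit norm (a zero vector is
    allowed only at b=0); (shell_id, direction, repeat_id) triples are unique.
    """

    bvals: np.ndarray          # (N,), s/mm^2
    bvecs: np.ndarray          # (N, 3), unit vectors
    shell_id: np.ndarray       # (N,), int
    repeat_id: np.ndarray      # (N,), int
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        shell_id = np.asarray(self.shell_id, dtype=int)
        repeat_id = np.asarray(self.repeat_id, dtype=int)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise ValueError(f"bvecs must be (N, 3), got {bvecs.shape}")
        n = len(bvals)
        if not (len(bvecs) == len(shell_id) == len(repeat_id) == n):
            raise ValueError("bvals, bvecs, shell_id, repeat_id length mismatch")
        if np.any(bvals < 0):
            raise ValueError("negative b-value")
        norms = np.linalg.norm(bvecs, axis=1)
        nonzero_b = bvals > 0
        if np.any(np.abs(norms[nonzero_b] - 1.0) > 1e-8):
            raise ValueError("non-unit bvec at nonzero b-value")
        zero_dir = norms < 1e-12
        if np.any(zero_dir & nonzero_b):
            raise ValueError("zero direction allowed only at b=0")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        object.__setattr__(self, "shell_id", shell_id)
        object.__setattr__(self, "repeat_id", repeat_id)

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def n_measurements(self) -> int:
        return len(self.bvals)

    @property
    def unique_bvals(self) -> np.ndarray:
        """Sorted distinct b-values."""
        return np.unique(np.round(self.bvals, 6))

    def subset(self, bvals: "set[float] | list | tuple",
               atol: float = 0.5) -> tuple["AcquisitionScheme", np.ndarray]:
        """Measurements whose b-value matches one of *bvals* within *atol*.

        Returns the sub-scheme and the boolean selector into this scheme.
        """
        wanted = np.asarray(sorted(bvals), dtype=float)
        sel = np.any(np.abs(self.bvals[:, None] - wanted[None, :]) <= atol, axis=1)
        missing = [b for b in wanted
                   if not np.any(np.abs(self.bvals - b) <= atol)]
        if missing:
            raise ValueError(f"b-values not present in scheme: {missing}")
        sub = AcquisitionScheme(self.bvals[sel], self.bvecs[sel],
                                self.shell_id[sel], self.repeat_id[sel])
        return sub, sel


def _repulsion_energy_and_grad(x: np.ndarray) -> tuple[float, np.ndarray]:
    """Electrostatic energy of antipodally symmetric point set on the sphere.

    ``x`` is (n, 3), not necessarily unit norm (normalised internally).
    Energy sums 1/r over all pairs among the 2n points {+-x_i}.
    """
    n = len(x)
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    u = x / norms
    energy = 0.0
    grad = np.zeros_like(u)
    for sign in (1.0, -1.0):
        d = u[:, None, :] - sign * u[None, :, :]    # (n, n, 3)
        r2 = np.sum(d * d, axis=-1)
        np.fill_diagonal(r2, np.inf)
        r = np.sqrt(r2)
        energy += 0.5 * np.sum(1.0 / r)
        # d(1/r)/du_i = -d / r^3, summed over j
        grad += -np.sum(d / r[..., None] ** 3, axis=1)
    # project gradient onto tangent plane of each unit vector
    grad -= u * np.sum(grad * u, axis=1, keepdims=True)
    return energy, grad


def electrostatic_directions(n: int, seed: int, n_iter: int = 2000,
                             step: float = 5e-3) -> np.ndarray:
    """Spread *n* unit vectors by electrostatic (Coulomb) repulsion of the
    antipodally symmetrised set; deterministic for a fixed seed.

    Projected gradient descent with adaptive step halving; adequate for the
    n <= 30 direction sets used here (min pairwise angle > 15 deg at n=30).
    """
    if n < 1:
        raise ValueError("need at least one direction")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    energy, grad = _repulsion_energy_and_grad(x)
    h = step
    for _ in range(n_iter):
        x_new = x - h * grad
        x_new /= np.linalg.norm(x_new, axis=1, keepdims=True)
        e_new, g_new = _repulsion_energy_and_grad(x_new)
        if e_new < energy:
            x, energy, grad = x_new, e_new, g_new
            h *= 1.1
        else:
            h *= 0.5
            if h < 1e-12:
                break
    # canonical sign: first component with |.| > 1e-10 made positive
    for v in x:
        for c in v:
            if abs(c) > 1e-10:
                if c < 0:
                    v *= -1.0
                break
    return x


def build_protocol(directions_per_shell: int = 30, repeats: int = 6,
                   seed: int = 1) -> AcquisitionScheme:
    """The 5-shell cardiac DKI scheme.

    The b=100 s/mm^2 shell always gets 3 directions x 12 repeats; the four
    higher shells get *directions_per_shell* directions x *repeats* repeats,
    so the total measurement count is ``36 + 4 * directions_per_shell * repeats``.
    Directions are electrostatic-repulsion sets, one independent set per shell
    (derived deterministically from *seed*).
    """
    if directions_per_shell < 6:
        raise ValueError(
            "directions_per_shell must be >= 6 (diffusion tensor has 6 "
            f"unknowns); got {directions_per_shell}")
    bvals, bvecs, shells, reps = [], [], [], []
    for s, b in enumerate(PROTOCOL_BVALS):
        if s == 0:
            ndir, nrep = 3, 12
        else:
            ndir, nrep = directions_per_shell, repeats
        dirs = electrostatic_directions(ndir, seed=seed * 1000 + s)
        for r in range(nrep):
            bvals.append(np.full(ndir, b))
            bvecs.append(dirs)
            shells.append(np.full(ndir, s, dtype=int))
            reps.append(np.full(ndir, r, dtype=int))
    return AcquisitionScheme(
        np.concatenate(bvals), np.vstack(bvecs),
        np.concatenate(shells), np.concatenate(reps),
        meta={"seed": seed, "directions_per_shell": directions_per_shell,
              "repeats": repeats},
    )


def write_gradient_table(scheme: AcquisitionScheme, prefix: str | Path) -> None:
    """Write FSL-style ``<prefix>.bval`` / ``<prefix>.bvec`` (bvecs as 3 rows)
    plus a JSON sidecar with the shell/repeat table."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(prefix.with_suffix(".bval"), "w") as f:
        f.write(" ".join(f"{b:.6g}" for b in scheme.bvals) + "\n")
    with open(prefix.with_suffix(".bvec"), "w") as f:
        for row in scheme.bvecs.T:
            f.write(" ".join(f"{v:.10f}" for v in row) + "\n")
    sidecar = {
        "shell_id": scheme.shell_id.tolist(),
        "repeat_id": scheme.repeat_id.tolist(),
        "meta": scheme.meta,
    }
    with open(prefix.with_suffix(".json"), "w") as f:
        json.dump(sidecar, f)


def read_gradient_table(prefix: str | Path) -> AcquisitionScheme:
    """Read FSL-style bval/bvec files written by :func:`write_gradient_table`.

    If the JSON sidecar is absent, shell ids are inferred from distinct
    b-values and repeat ids from recurrence of (b, direction) pairs.
    """
    prefix = Path(prefix)
    bvals = np.loadtxt(prefix.with_suffix(".bval"), ndmin=1)
    bvecs = np.loadtxt(prefix.with_suffix(".bvec"), ndmin=2)
    if bvecs.shape[0] != 3:
        raise GradientTableError(
            f"bvec file must have 3 rows, got {bvecs.shape[0]}")
    bvecs = bvecs.T
    if len(bvals) != len(bvecs):
        raise GradientTableError(
            f"bval count ({len(bvals)}) does not match bvec column count "
            f"({len(bvecs)})")
    sidecar = prefix.with_suffix(".json")
    if sidecar.exists():
        with open(sidecar) as f:
            extra = json.load(f)
        shell_id = np.asarray(extra["shell_id"], dtype=int)
        repeat_id = np.asarray(extra["repeat_id"], dtype=int)
        meta = extra.get("meta", {})
    else:
        shells = np.unique(np.round(bvals, 1))
        shell_id = np.searchsorted(shells, np.round(bvals, 1))
        repeat_id = np.zeros(len(bvals), dtype=int)
        seen: dict[tuple, int] = {}
        for i in range(len(bvals)):
            key = (round(bvals[i], 1), tuple(np.round(bvecs[i], 6)))
            repeat_id[i] = seen.get(key, 0)
            seen[key] = repeat_id[i] + 1
        meta = {}
    return AcquisitionScheme(bvals, bvecs, shell_id, repeat_id, meta=meta)
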