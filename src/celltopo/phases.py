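"""Ground-truth machinery: adhesion-regime phase labels and fast synthetic
pattern fixtures.

The regime labeler assigns each adhesion triple (J_BB, J_OO, J_BO) one of
the pattern phases (i..xii without proliferation, v-vii & ix-xv with) by an
ordered rule table shipped as editable JSON data — a deterministic
surrogate for manual annotation of steady-state snapshots. The pattern
generator builds idealized labeled point clouds of every pattern class
(dispersed, sorted, intermixed, checkerboard, stripes, hexagonal spots,
core-shell, labyrinth) so every downstream stage can be exercised without
long simulations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "CONSTANT_LABELS",
    "PROLIFERATION_LABELS",
    "PATTERN_KINDS",
    "PhaseLabel",
    "load_rule_table",
    "regime_label",
    "generate_pattern",
]

CONSTANT_LABELS = ("i", "ii", "iii", "iv", "v", "vi",
                   "vii", "viii", "ix", "x", "xi", "xii")
PROLIFERATION_LABELS = ("v", "vi", "vii", "ix", "x",
                        "xi", "xii", "xiii", "xiv", "xv")
PATTERN_KINDS = ("dispersed", "sorted", "intermixed", "checkerboard",
                 "stripes", "hex_spots", "core_shell", "labyrinth")


@dataclass(frozen=True)
class PhaseLabel:
    code: str
    description: str


def load_rule_table(path: str | None = None) -> dict:
    if path is None:
        text = resources.files("celltopo").joinpath(
            "data/regime_rules.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return json.loads(text)


_DEFAULT_RULES = None


def _operand(spec, env):
    if isinstance(spec, (int, float)):
        return float(spec)
    if isinstance(spec, str):
        return env[spec]
    val = env[spec["var"]]
    return val * spec.get("scale", 1.0) + spec.get("offset", 0.0)


_OPS = {
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
}


def regime_label(j_bb: float, j_oo: float, j_bo: float,
                 proliferation: bool = False,
                 rules: dict | None = None,
                 as_label: bool = False):
    """Phase label for one adhesion triple; first matching rule wins.

    The rule tables are total: the last rule of each regime has no
    conditions, so every triple receives exactly one label.
    """
    if min(j_bb, j_oo, j_bo) < 0:
        raise ValueError("adhesion magnitudes must be nonnegative")
    global _DEFAULT_RULES
    if rules is None:
        if _DEFAULT_RULES is None:
            _DEFAULT_RULES = load_rule_table()
        rules = _DEFAULT_RULES
    env = {
        "J_BB": j_bb, "J_OO": j_oo, "J_BO": j_bo,
        "diff": j_bb - j_oo, "absdiff": abs(j_bb - j_oo),
        "max_homo": max(j_bb, j_oo), "min_homo": min(j_bb, j_oo),
    }
    table = rules["proliferation" if proliferation else "constant"]
    for rule in table:
        if all(_OPS[op](_operand(lhs, env), _operand(rhs, env))
               for lhs, op, rhs in rule["all"]):
            code = rule["label"]
            if as_label:
                return PhaseLabel(code, rules["labels"].get(code, ""))
            return code
    raise RuntimeError("rule table is not total")  # pragma: no cover


# ---------------------------------------------------------------------------
# synthetic pattern fixtures

def _hex_lattice_disk(radius: float, spacing: float = 1.0,
                      center=(0.0, 0.0)) -> np.ndarray:
    """Triangular-lattice points inside a disk."""
    pts = []
    dy = spacing * np.sqrt(3) / 2
    nrows = int(radius / dy) + 2
    ncols = int(radius / spacing) + 2
    for row in range(-nrows, nrows + 1):
        xoff = 0.5 * spacing if row % 2 else 0.0
        y = row * dy
        for col in range(-ncols, ncols + 1):
            x = col * spacing + xoff
            if x * x + y * y <= radius * radius:
                pts.append((x + center[0], y + center[1]))
    return np.array(pts)


def _disk_radius(n: int, spacing: float = 1.0) -> float:
    density = 2.0 / (np.sqrt(3) * spacing**2)
    return float(np.sqrt(n / (np.pi * density))) + spacing


def _split_counts(n, fractions):
    n0 = int(round(n * fractions[0]))
    return n0, n - n0


def generate_pattern(kind: str, n_cells: int = 200, fractions=(0.6, 0.4),
                     noise_scale: float = 0.05, seed: int = 0,
                     box_halfwidth: float = 20.0):
    """Labeled point cloud realizing one idealized pattern class.

    Returns ``(positions, types)`` with types as 0 (majority/blue) and
    1 (minority/orange). The realized cell count can differ slightly from
    ``n_cells`` for lattice-based kinds. Gaussian positional jitter of
    scale ``noise_scale`` is applied to every kind; deterministic per seed.
    """
    if kind not in PATTERN_KINDS:
        raise ValueError(f"unknown pattern kind {kind!r}")
    if n_cells < 10:
        raise ValueError("n_cells must be >= 10")
    rng = np.random.default_rng(seed)
    nb, no = _split_counts(n_cells, fractions)

    if kind == "dispersed":
        half = box_halfwidth
        pts = []
        while len(pts) < n_cells:
            cand = rng.uniform(-half, half, size=2)
            if all((cand[0] - p[0])**2 + (cand[1] - p[1])**2 > 1.2**2
                   for p in pts[-200:]):
                pts.append(tuple(cand))
        pos = np.array(pts)
        types = np.zeros(n_cells, dtype=np.int8)
        types[rng.permutation(n_cells)[:no]] = 1

    elif kind == "sorted":
        rb, ro = _disk_radius(nb), _disk_radius(no)
        gap = 2.0
        pb = _hex_lattice_disk(rb, center=(-(rb + gap / 2), 0.0))[:nb]
        po = _hex_lattice_disk(ro, center=(ro + gap / 2, 0.0))[:no]
        pos = np.vstack([pb, po])
        types = np.r_[np.zeros(len(pb), np.int8), np.ones(len(po), np.int8)]

    elif kind == "intermixed":
        lat = _hex_lattice_disk(_disk_radius(n_cells))
        pos = lat[:n_cells] if len(lat) >= n_cells else lat
        types = np.zeros(len(pos), dtype=np.int8)
        types[rng.permutation(len(pos))[:int(round(len(pos) * fractions[1]))]] = 1

    elif kind == "checkerboard":
        m = int(np.ceil(np.sqrt(n_cells)))
        ix, iy = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
        pos = np.column_stack([(ix - m / 2).ravel(), (iy - m / 2).ravel()]).astype(float)
        types = ((ix + iy) % 2).ravel().astype(np.int8)
        pos, types = pos[:n_cells], types[:n_cells]

    elif kind == "stripes":
        m = int(np.ceil(np.sqrt(n_cells)))
        ix, iy = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
        pos = np.column_stack([(ix - m / 2).ravel(), (iy - m / 2).ravel()]).astype(float)
        band = 2  # rows per stripe: stripes 1-2 cells thick
        types = ((iy // band) % 2).ravel().astype(np.int8)
        pos, types = pos[:n_cells], types[:n_cells]

    elif kind == "hex_spots":
        # minority cells sit on a coarse triangular lattice of spot centers,
        # majority fills the surrounding sea
        spot_spacing = 4.0
        r = _disk_radius(n_cells)
        centers = _hex_lattice_disk(r - 1.0, spacing=spot_spacing)
        sea = _hex_lattice_disk(r)
        keep = np.ones(len(sea), dtype=bool)
        for c in centers:
            keep &= np.einsum("ij,ij->i", sea - c, sea - c) > 1.0
        pos = np.vstack([sea[keep], centers])
        types = np.r_[np.zeros(keep.sum(), np.int8),
                      np.ones(len(centers), np.int8)]

    elif kind == "core_shell":
        ro = _disk_radius(no)
        rb = np.sqrt(ro**2 + nb * np.sqrt(3) / 2 / np.pi) + 1.0
        core = _hex_lattice_disk(ro)[:no]
        shell_full = _hex_lattice_disk(rb)
        dist = np.sqrt(np.einsum("ij,ij->i", shell_full, shell_full))
        shell = shell_full[dist > ro + 0.5][:nb]
        pos = np.vstack([shell, core])
        types = np.r_[np.zeros(len(shell), np.int8), np.ones(len(core), np.int8)]

    else:  # labyrinth
        lat = _hex_lattice_disk(_disk_radius(n_cells))
        k = 2 * np.pi / 4.0  # stripe wavelength ~ 4 cell diameters
        field = np.zeros(len(lat))
        for _ in range(3):
            phi = rng.uniform(0, 2 * np.pi)
            psi = rng.uniform(0, 2 * np.pi)
            field += np.sin(k * (lat[:, 0] * np.cos(phi)
                                 + lat[:, 1] * np.sin(phi)) + psi)
        thresh = np.quantile(field, 1.0 - fractions[1])
        pos = lat[:n_cells]
        types = (field[:n_cells] > thresh[()]).astype(np.int8)

    pos = pos + noise_scale * rng.standard_normal(pos.shape)
    return pos, types
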