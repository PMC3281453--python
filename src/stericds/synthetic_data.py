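"""Synthetic inputs with known ground truth: toy molecules and trap data.

Ecology side.  Pitfall-trap counts are negative-binomially dispersed around a
log-linear mean:

    log mu = baseline + site_effect + [after spray] * beta . (d - d_ref)

where ``d`` is the sprayed insecticide's descriptor vector (Ds, logP, Pe, S,
logKoc), ``d_ref`` centres each descriptor on its generative range so the
baseline is interpretable as the pre-spray mean, and ``beta`` carries the
field-observed sign pattern (negative Ds/Pe/logKoc, positive logP/S).  The
default effect sizes are standardized: each coefficient moves the log-mean by
0.4 per standard deviation of its descriptor.  Individuals are assigned to a
238-species pool multinomially with log-series weights, reproducing the
heavy-tailed dominance structure of real staphylinid assemblages (a top-9
share near 45%).  Default design: 12 sites x 5 years x 10 spray events x
{before, after}.

Molecular side.  Deterministic toy molecules (alkane chains/rings, polar and
apolar probes, an N-acetylglucosamine-like monomer) with full topology and
neutral integer-summed partial charges, guaranteed parameterizable by the
builtin minimal set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structures_io import (
    Atom,
    Structure,
    build_chitin_host,
    derive_angles,
    derive_torsions,
)

# descriptor generative ranges (uniform unless noted) and their centres
DESCRIPTOR_RANGES = {
    "Ds": (15.0, 60.0),        # percent
    "logP": (1.0, 7.0),        # dimensionless
    "Pe": (24.0, 2000.0),      # hours
    "S": (0.001, 150.0),       # mg/L, log-uniform
    "logKoc": (2.0, 5.0),      # dimensionless
}
DESCRIPTOR_REFERENCE = {
    "Ds": 37.5, "logP": 4.0, "Pe": 1012.0,
    "S": 12.58,                # mean of the log-uniform range
    "logKoc": 3.5,
}

# default effects on the log-mean: ~0.4 per descriptor SD, signs as observed
# in the field (abundance falls with Ds, Pe, logKoc; rises with logP, S)
DEFAULT_BETAS = {
    "Ds": -0.03, "logP": 0.23, "Pe": -0.0007, "S": 0.014, "logKoc": -0.46,
}


@dataclass
class EcoSimParams:
    """Design and effect parameters of the trap-count simulator."""

    n_sites: int = 12
    n_treatments_per_year: int = 10
    n_years: int = 5
    n_species_pool: int = 238
    baseline_log_abundance: float = math.log(5.2)
    site_effect_sd: float = 0.3
    betas: dict = field(default_factory=lambda: dict(DEFAULT_BETAS))
    dispersion: float = 2.0        # negative-binomial size parameter
    logseries_x: float = 0.9999
    seed: int = 0

    def __post_init__(self):
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.n_sites < 2:
            raise ValueError("need at least two sites")


def gen_descriptor_table(n_insecticides: int, seed: int) -> pd.DataFrame:
    """Random descriptor table over the declared generative ranges,
    deterministic given *seed*; index is the insecticide name."""
    if n_insecticides < 2:
        raise ValueError("need at least two insecticides")
    rng = np.random.default_rng(seed)
    lo_s, hi_s = DESCRIPTOR_RANGES["S"]
    table = pd.DataFrame({
        "Ds": rng.uniform(*DESCRIPTOR_RANGES["Ds"], n_insecticides),
        "logP": rng.uniform(*DESCRIPTOR_RANGES["logP"], n_insecticides),
        "Pe": rng.uniform(*DESCRIPTOR_RANGES["Pe"], n_insecticides),
        "S": np.exp(rng.uniform(math.log(lo_s), math.log(hi_s),
                                n_insecticides)),
        "logKoc": rng.uniform(*DESCRIPTOR_RANGES["logKoc"], n_insecticides),
    }, index=[f"ins{k + 1:02d}" for k in range(n_insecticides)])
    table.index.name = "insecticide"
    return table


def logseries_weights(n_species: int, x: float) -> np.ndarray:
    """Normalized log-series relative abundances w_k proportional to x^k/k."""
    k = np.arange(1, n_species + 1, dtype=float)
    w = x ** k / k
    return w / w.sum()


def _descriptor_effect(row: pd.Series, betas: dict) -> float:
    return sum(betas[c] * (row[c] - DESCRIPTOR_REFERENCE[c]) for c in betas)


def gen_trap_dataset(params: EcoSimParams, descriptors: pd.DataFrame,
                     assign_species: bool = True):
    """Simulate a before/after pitfall-trap dataset.

    Spray events cycle through the descriptor table so every insecticide is
    applied a balanced number of times across sites and years.  Returns
    ``(dataset, truth)`` where *truth* records every generative quantity.
    With ``assign_species=False`` counts are kept at the assessment level
    (one pseudo-species row per assessment), which is faster and sufficient
    for abundance analyses.
    """
    rng = np.random.default_rng(params.seed)
    site_effects = rng.normal(0.0, params.site_effect_sd, params.n_sites)
    weights = logseries_weights(params.n_species_pool, params.logseries_x)
    n_ins = len(descriptors)
    effects = {name: _descriptor_effect(row, params.betas)
               for name, row in descriptors.iterrows()}
    names = list(descriptors.index)

    rows = []
    counter = 0
    for site in range(params.n_sites):
        for year in range(params.n_years):
            for event in range(params.n_treatments_per_year):
                ins = names[counter % n_ins]
                counter += 1
                date = f"y{year + 1}e{event + 1:02d}"
                for phase in ("before", "after"):
                    log_mu = (params.baseline_log_abundance
                              + site_effects[site])
                    if phase == "after":
                        log_mu += effects[ins]
                    mu = math.exp(log_mu)
                    p = params.dispersion / (params.dispersion + mu)
                    total = int(rng.negative_binomial(params.dispersion, p))
                    if assign_species:
                        if total > 0:
                            sp_counts = rng.multinomial(total, weights)
                            for sp in np.nonzero(sp_counts)[0]:
                                rows.append((f"site{site + 1:02d}", date,
                                             phase, ins,
                                             f"sp{sp + 1:03d}",
                                             int(sp_counts[sp])))
                        else:
                            # keep the assessment visible with a zero record
                            rows.append((f"site{site + 1:02d}", date, phase,
                                         ins, "sp001", 0))
                    else:
                        rows.append((f"site{site + 1:02d}", date, phase, ins,
                                     "all", total))
    dataset = pd.DataFrame(
        rows, columns=["site", "date", "phase", "insecticide",
                       "species", "count"])
    truth = {
        "betas": dict(params.betas),
        "reference": dict(DESCRIPTOR_REFERENCE),
        "baseline_log_abundance": params.baseline_log_abundance,
        "site_effects": site_effects.tolist(),
        "dispersion": params.dispersion,
        "insecticide_effects": effects,
        "species_weights": weights.tolist() if assign_species else None,
    }
    return dataset, truth


def gen_abundance_response(descriptors: pd.DataFrame, seed: int,
                           betas: dict | None = None,
                           baseline: float = 5.2,
                           noise_sd: float = 1.0):
    """Linear-model abundance response for regression/partial-correlation
    recovery studies:  N = baseline + beta . (d - d_ref) + Normal(0, sd).

    Returns ``(N, truth)``.
    """
    betas = dict(betas or DEFAULT_BETAS)
    rng = np.random.default_rng(seed)
    effect = np.array([_descriptor_effect(row, betas)
                       for _, row in descriptors.iterrows()])
    n = baseline + effect + rng.normal(0.0, noise_sd, len(descriptors))
    truth = {"betas": betas, "baseline": baseline, "noise_sd": noise_sd,
             "reference": dict(DESCRIPTOR_REFERENCE)}
    return n, truth


# ---------------------------------------------------------------------------
# toy molecules
# ---------------------------------------------------------------------------

TEMPLATES = ("chain", "ring", "polar-probe", "apolar-probe", "chitin-monomer")

TEMPLATE_SIZE_BOUNDS = {
    "chain": (1, 12), "ring": (3, 10), "polar-probe": (1, 8),
    "apolar-probe": (1, 12), "chitin-monomer": (1, 1),
}


@dataclass(frozen=True)
class MoleculeSpec:
    """Recipe for a deterministic toy molecule."""

    template: str
    size: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.template not in TEMPLATES:
            raise ValueError(f"unknown template {self.template!r}")
        lo, hi = TEMPLATE_SIZE_BOUNDS[self.template]
        if not lo <= self.size <= hi:
            raise ValueError(
                f"size {self.size} outside [{lo}, {hi}] for "
                f"{self.template!r}")


_CH = 1.09
_OH = 0.96


def _frame(d0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to d0 and each other."""
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(d0, ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(d0, ref)
    u /= np.linalg.norm(u)
    return u, np.cross(d0, u)


def _fill_dirs(existing: list[np.ndarray], n_needed: int) -> list[np.ndarray]:
    """Approximate tetrahedral directions avoiding the existing bonds."""
    if not existing:
        t = math.acos(-1.0 / 3.0)
        base = [np.array([0.0, 0.0, 1.0])]
        for k in range(3):
            ang = 2.0 * math.pi * k / 3.0
            base.append(np.array([math.sin(t) * math.cos(ang),
                                  math.sin(t) * math.sin(ang),
                                  math.cos(t)]))
        return base[:n_needed]
    d0 = -np.sum(existing, axis=0)
    nrm = np.linalg.norm(d0)
    d0 = d0 / nrm if nrm > 1e-8 else np.array([0.0, 0.0, 1.0])
    if n_needed == 1:
        return [d0]
    u, w = _frame(d0)
    half = math.radians(109.47 / 2.0)
    if n_needed == 2:
        return [math.cos(half) * d0 + math.sin(half) * u,
                math.cos(half) * d0 - math.sin(half) * u]
    tilt = math.radians(70.53)
    dirs = []
    for k in range(n_needed):
        ang = 2.0 * math.pi * k / n_needed
        dirs.append(math.cos(tilt) * d0
                    + math.sin(tilt) * (math.cos(ang) * u + math.sin(ang) * w))
    return dirs


def _add_hydrogens(elements, coords, bonds, valences) -> None:
    """Append hydrogens (in place) until each heavy atom reaches its
    valence."""
    n_heavy = len(elements)
    for i in range(n_heavy):
        if elements[i] == "H":
            continue
        nbrs = [j for a, b, _ in bonds for j in ((b,) if a == i else
                                                 (a,) if b == i else ())]
        need = valences.get(elements[i], 4) - len(nbrs)
        if need <= 0:
            continue
        existing = [np.asarray(coords[j]) - np.asarray(coords[i])
                    for j in nbrs]
        existing = [e / np.linalg.norm(e) for e in existing]
        length = _OH if elements[i] in ("O", "N") else _CH
        for d in _fill_dirs(existing, need):
            coords.append(np.asarray(coords[i]) + length * d)
            elements.append("H")
            bonds.append((i, len(elements) - 1, 1))


def _backbone(n: int, bond: float = 1.526,
              angle_deg: float = 111.0) -> list[np.ndarray]:
    half = math.radians(angle_deg) / 2.0
    dx, dz = bond * math.sin(half), bond * math.cos(half)
    return [np.array([k * dx, 0.0, (k % 2) * dz]) for k in range(n)]


def _finish(elements, coords, bonds, charges, name, seed) -> Structure:
    rng = np.random.default_rng(seed)
    jitter = rng.normal(0.0, 0.01, (len(elements), 3))
    # exact neutrality: spread any charge remainder over all atoms
    charges = np.asarray(charges, dtype=float)
    charges -= charges.sum() / len(charges)
    atoms = [Atom(el, tuple(np.asarray(c) + j), partial_charge=float(q))
             for el, c, j, q in zip(elements, coords, jitter, charges)]
    s = Structure(atoms, bonds, name=name)
    s.angles = derive_angles(s.n_atoms, s.bonds)
    s.torsions = derive_torsions(s.n_atoms, s.bonds)
    return s


def gen_molecule(spec: MoleculeSpec) -> Structure:
    """Build the toy molecule described by *spec* (pure function of the
    spec, including its seed, which only jitters coordinates slightly)."""
    valences = {"C": 4, "O": 2, "N": 3}
    if spec.template == "chitin-monomer":
        return build_chitin_host(1)
    if spec.template in ("chain", "apolar-probe"):
        n = spec.size
        coords = _backbone(n)
        elements = ["C"] * n
        bonds = [(k, k + 1, 1) for k in range(n - 1)]
        _add_hydrogens(elements, coords, bonds, valences)
        charges = [0.0] * len(elements)
        return _finish(elements, coords, bonds, charges,
                       f"{spec.template}{n}", spec.seed)
    if spec.template == "ring":
        n = spec.size
        r = 1.526 / (2.0 * math.sin(math.pi / n))
        coords = [np.array([r * math.cos(2 * math.pi * k / n),
                            r * math.sin(2 * math.pi * k / n),
                            0.25 * (-1) ** k]) for k in range(n)]
        elements = ["C"] * n
        bonds = [(k, (k + 1) % n, 1) for k in range(n)]
        _add_hydrogens(elements, coords, bonds, valences)
        charges = [0.0] * len(elements)
        return _finish(elements, coords, bonds, charges,
                       f"ring{n}", spec.seed)
    # polar-probe: HO-(CH2)size-OH diol with explicit partial charges
    n = spec.size
    coords = _backbone(n + 2, bond=1.45)
    elements = ["O"] + ["C"] * n + ["O"]
    bonds = [(k, k + 1, 1) for k in range(n + 1)]
    _add_hydrogens(elements, coords, bonds, valences)
    charges = []
    for k, el in enumerate(elements):
        if el == "O":
            charges.append(-0.40)
        elif el == "C" and any(elements[j] == "O"
                               for a, b, _ in bonds
                               for j in ((b,) if a == k else
                                         (a,) if b == k else ())):
            charges.append(0.10)
        elif el == "H":
            # hydroxyl hydrogens: bonded to O
            nbr = next(j for a, b, _ in bonds
                       for j in ((b,) if a == k else (a,) if b == k else ()))
            charges.append(0.30 if elements[nbr] == "O" else 0.0)
        else:
            charges.append(0.0)
    return _finish(elements, coords, bonds, charges,
                   f"polar-probe{n}", spec.seed)
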