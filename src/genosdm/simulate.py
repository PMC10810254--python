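"""Synthetic study systems for end-to-end testing of the pipeline.

The generator emulates the structure the analysis assumes: a handful of
ancestral populations drifted apart under the Balding–Nichols model, admixed
individuals spread over several ranges with range-specific ancestry mixes,
and a genotype–environment association created by giving each genetic
cluster its own environmental optimum (a Gaussian niche in environment
space). One range can be truncated to a sub-rectangle of its landscape to
emulate a recently introduced, non-equilibrium population that occupies only
part of its suitable habitat.

Everything is driven by a single :class:`ScenarioSpec` seed through named
substreams, so two runs with the same spec are bit-identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter

from .admixture import AncestryMatrix
from .genotypes import GenotypeMatrix
from .grids import EnvGrid
from .occurrences import OccurrenceSet

__all__ = ["ScenarioSpec", "ScenarioData", "generate_landscape",
           "generate_genotypes", "place_occurrences", "generate_scenario",
           "qualitative_pattern_spec"]


def qualitative_pattern_spec(seed: int = 0) -> "ScenarioSpec":
    """Scenario used to probe the qualitative cluster-niche pattern.

    Cluster optima are ordered along a single environmental axis with the
    warm pair close together (0.6, 0.68) and the cool outlier far away
    (0.2) — the geometry of a cool-specialist cluster versus two similar
    warm clusters. The last range is a geographically restricted,
    non-equilibrium population whose founder mix essentially lacks the cool
    cluster, so that cluster's niche is the novel habitat: models built
    from it should rank first in the range-expansion table, and the warm
    pair should overlap more with each other than either does with the
    outlier. Sized for quick replicated runs (40x40 grids, 3 layers, 400
    SNPs, 150 individuals per range).
    """
    return ScenarioSpec(
        grid_size=(40, 40), n_env_layers=3, n_snps=400,
        n_individuals_per_range=150,
        cluster_optima=np.array([[0.2, 0.5, 0.5],
                                 [0.6, 0.5, 0.5],
                                 [0.68, 0.5, 0.5]]),
        niche_sd=np.array([0.12, 0.08, 0.08]),
        dirichlet_alpha=np.array([[1.0, 1.0, 1.0],
                                  [1.0, 1.0, 1.0],
                                  [0.02, 1.0, 1.0]]),
        truncation_box=(8, 32, 0, 40),
        seed=seed)

_RANGE_NAMES = ["native", "invaded_old", "invaded_new"]


def _default_optima(L: int, n_layers: int) -> np.ndarray:
    """Cluster optima spread along the first environmental axis.

    Clusters are ordered from cool/dry-analogue (low values) to warm/wet
    (high values): evenly spaced on [0.25, 0.75] along layer 0, neutral
    (0.5) elsewhere.
    """
    opt = np.full((L, n_layers), 0.5)
    opt[:, 0] = np.linspace(0.25, 0.75, L) if L > 1 else 0.5
    return opt


@dataclass
class ScenarioSpec:
    """Parameters of a synthetic study system.

    Defaults are a scaled-down analogue of a three-range invasion study:
    3 ranges (the last one truncated / non-equilibrium), 60x60 landscapes
    with 5 environmental layers on [0, 1], L=3 ancestral populations at
    Balding–Nichols drift F=0.3, 2000 biallelic SNPs and 200 individuals per
    range. Clusters are environmental specialists (niche_sd = 0.08 on the
    unit environmental range), so each range's realized niche is a compact,
    separable subset of the landscape. The last range's ancestry mix nearly
    lacks the first cluster, mirroring a founder population that did not
    carry it.
    """

    n_ranges: int = 3
    grid_size: tuple = (60, 60)
    n_env_layers: int = 5
    L_true: int = 3
    n_snps: int = 2000
    bn_F: float = 0.3
    n_individuals_per_range: int = 200
    cluster_optima: np.ndarray | None = None
    niche_sd: float | np.ndarray = 0.08
    dirichlet_alpha: np.ndarray | None = None
    truncation_box: tuple | None = None  # (row0, row1, col0, col1), half-open
    noise_amplitude: float = 0.3  # local noise relative to the gradient span
    layer_range: tuple = (0.0, 1.0)
    cell_size: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_ranges, self.n_env_layers, self.L_true, self.n_snps,
               self.n_individuals_per_range) < 1:
            raise ValueError("all counts must be positive")
        if not 0.0 < self.bn_F < 1.0:
            raise ValueError("bn_F must be in (0, 1)")
        if self.cluster_optima is None:
            self.cluster_optima = _default_optima(self.L_true,
                                                  self.n_env_layers)
        self.cluster_optima = np.asarray(self.cluster_optima, dtype=float)
        if self.cluster_optima.shape != (self.L_true, self.n_env_layers):
            raise ValueError("cluster_optima must be L_true x n_env_layers")
        self.niche_sd = np.broadcast_to(
            np.asarray(self.niche_sd, dtype=float), (self.L_true,)).copy()
        if np.any(self.niche_sd <= 0):
            raise ValueError("niche_sd must be positive")
        if self.dirichlet_alpha is None:
            alpha = np.ones((self.n_ranges, self.L_true))
            if self.n_ranges > 1 and self.L_true > 1:
                alpha[-1, 0] = 0.15  # founder effect: first cluster rare
            self.dirichlet_alpha = alpha
        self.dirichlet_alpha = np.asarray(self.dirichlet_alpha, dtype=float)
        if self.dirichlet_alpha.shape != (self.n_ranges, self.L_true):
            raise ValueError("dirichlet_alpha must be n_ranges x L_true")
        if self.truncation_box is None and self.n_ranges > 1:
            rows, cols = self.grid_size
            # last range restricted to the high-layer0 (eastern) part of the
            # gradient: the environments of the clusters actually present
            # there remain available, while the first cluster's optimum lies
            # in unoccupied (cooler/drier-analogue) conditions
            self.truncation_box = (0, rows, cols // 3, cols)
        if self.truncation_box is not None:
            r0, r1, c0, c1 = self.truncation_box
            rows, cols = self.grid_size
            if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
                raise ValueError("truncation_box must lie inside the grid")

    def range_name(self, i: int) -> str:
        return _RANGE_NAMES[i] if i < len(_RANGE_NAMES) else f"range{i}"

    @property
    def truncated_range(self) -> int | None:
        """Index of the non-equilibrium range (the last), if any."""
        return self.n_ranges - 1 if (self.truncation_box is not None
                                     and self.n_ranges > 1) else None

    def to_json(self) -> str:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return json.dumps(d, indent=1)


def _rng(spec: ScenarioSpec, *tag: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed] + list(tag))


def generate_landscape(spec: ScenarioSpec, range_index: int) -> EnvGrid:
    """One range's environmental layers: gradient + smoothed noise + coast.

    Each layer is a large-scale linear gradient (direction varying by layer)
    plus spatially smoothed Gaussian noise, min–max rescaled to
    ``spec.layer_range``. A fraction of border cells is masked to emulate a
    coastline.
    """
    rows, cols = spec.grid_size
    rng = _rng(spec, 2, range_index)
    dir_rng = _rng(spec, 4)  # gradient directions shared by all ranges
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    rn = rr / max(rows - 1, 1)
    cn = cc / max(cols - 1, 1)
    lo, hi = spec.layer_range
    layers = []
    names = []
    for l in range(spec.n_env_layers):
        if l == 0:
            grad = cn  # west -> east
        elif l == 1:
            grad = rn  # north -> south
        else:
            # same large-scale direction in every range (shared "climate
            # structure"); range-specific noise still differentiates ranges
            theta = dir_rng.uniform(0, 2 * np.pi)
            grad = np.cos(theta) * cn + np.sin(theta) * rn
        noise = gaussian_filter(rng.standard_normal((rows, cols)), sigma=3.0)
        noise = (noise - noise.mean()) / (noise.std() + 1e-12)
        v = grad + spec.noise_amplitude * noise * (grad.max() - grad.min()
                                                   + 1e-12)
        # robust rescale (1st-99th percentile) so the value distribution is
        # stable across noise draws; min-max would be squeezed by extremes
        q1, q99 = np.percentile(v, [1, 99])
        v = np.clip((v - q1) / (q99 - q1 + 1e-12), 0.0, 1.0)
        layers.append(lo + v * (hi - lo))
        names.append(f"env{l + 1}")

    # coastline: mask border cells where a smooth field dips low
    coast = gaussian_filter(rng.standard_normal((rows, cols)), sigma=4.0)
    coast = (coast - coast.mean()) / (coast.std() + 1e-12)
    edge_dist = np.minimum(np.minimum(rr, rows - 1 - rr),
                           np.minimum(cc, cols - 1 - cc))
    mask = ~((edge_dist < max(2, rows // 12)) & (coast < -0.3))
    vals = np.stack(layers)
    return EnvGrid(names, vals, mask, origin_x=0.0,
                   origin_y=rows * spec.cell_size, cell_size=spec.cell_size)


def generate_genotypes(spec: ScenarioSpec
                       ) -> tuple[GenotypeMatrix, AncestryMatrix, np.ndarray]:
    """Genotypes, true ancestry proportions and true ancestral frequencies.

    Ancestral frequencies follow the Balding–Nichols model: shared ancestral
    frequencies ~ Uniform(0.05, 0.95), per-population frequencies
    ~ Beta(pi (1-F)/F, (1-pi)(1-F)/F). Each individual's q is Dirichlet with
    its range's concentration vector and its dosages are
    Binomial(2, sum_l q_l p_ls).
    """
    rng = _rng(spec, 1)
    L, m = spec.L_true, spec.n_snps
    pi = rng.uniform(0.05, 0.95, size=m)
    ratio = (1.0 - spec.bn_F) / spec.bn_F
    P = rng.beta(pi * ratio, (1.0 - pi) * ratio, size=(L, m))
    P = np.clip(P, 1e-6, 1.0 - 1e-6)

    qs, ids, ranges = [], [], []
    for r in range(spec.n_ranges):
        alpha = spec.dirichlet_alpha[r]
        if np.isinf(alpha).any():
            q = np.zeros((spec.n_individuals_per_range, L))
            q[:, int(np.argmax(alpha))] = 1.0  # degenerate one-hot mix
        else:
            q = rng.dirichlet(alpha, size=spec.n_individuals_per_range)
        qs.append(q)
        name = spec.range_name(r)
        ids.extend(f"{name}_i{j:04d}"
                   for j in range(spec.n_individuals_per_range))
        ranges.extend([name] * spec.n_individuals_per_range)
    Q = np.vstack(qs)
    Q = Q / Q.sum(axis=1, keepdims=True)
    F = Q @ P
    dosages = rng.binomial(2, F).astype(float)
    g = GenotypeMatrix(dosages, ids,
                       [f"snp{j:05d}" for j in range(m)],
                       np.asarray(ranges))
    truth = AncestryMatrix(Q, cluster=np.argmax(Q, axis=1) + 1,
                           sample_ids=ids)
    return g, truth, P


def place_occurrences(spec: ScenarioSpec, grid: EnvGrid,
                      q_truth: AncestryMatrix, range_index: int,
                      range_labels=None, sample_ids=None) -> OccurrenceSet:
    """Sample occurrence locations for one range's individuals.

    Each individual settles in a cell with probability proportional to a
    Gaussian suitability kernel around its dominant cluster's environmental
    optimum (ties broken toward the lowest cluster index); the truncated
    range is restricted to its truncation box. Coordinates get a small
    within-cell jitter so records are distinct but snap back to the sampled
    cell. Records carry the individual id linking them to the genotypes.
    """
    name = spec.range_name(range_index)
    if range_labels is None:
        if q_truth.sample_ids is None:
            raise ValueError("need range_labels or sample_ids to select "
                             "this range's individuals")
        range_labels = np.array([s.rsplit("_i", 1)[0]
                                 for s in q_truth.sample_ids])
    sel = np.nonzero(np.asarray(range_labels) == name)[0]
    if sel.size == 0:
        raise ValueError(f"no individuals belong to range {name!r}")
    q = q_truth.q[sel]
    ids = ([q_truth.sample_ids[i] for i in sel]
           if q_truth.sample_ids is not None else
           [f"{name}_i{j:04d}" for j in range(sel.size)])

    allowed = grid.mask.copy()
    if spec.truncated_range == range_index:
        r0, r1, c0, c1 = spec.truncation_box
        box = np.zeros_like(allowed)
        box[r0:r1, c0:c1] = True
        allowed &= box
        if not allowed.any():
            raise ValueError("truncation_box contains no valid cells")
    rr, cc = np.nonzero(allowed)
    env = grid.values[:, rr, cc].T  # (n_cells, n_layers)

    rng = _rng(spec, 3, range_index)
    # argmax with ties toward the lowest cluster index
    dominant = np.argmax(q, axis=1)
    xs, ys, out_ids = [], [], []
    for cl in range(spec.L_true):
        members = np.nonzero(dominant == cl)[0]
        if members.size == 0:
            continue
        d2 = ((env - spec.cluster_optima[cl]) ** 2).sum(axis=1)
        sd = spec.niche_sd[cl]
        if np.isinf(sd):
            w = np.ones(len(env))
        else:
            logw = -d2 / (2.0 * sd**2)
            w = np.exp(logw - logw.max())
        w = w / w.sum()
        cells = rng.choice(len(rr), size=members.size, p=w)
        jitter = rng.uniform(-0.4, 0.4, size=(members.size, 2))
        x, y = grid.cell_center(rr[cells], cc[cells])
        xs.append(x + jitter[:, 0] * spec.cell_size)
        ys.append(y + jitter[:, 1] * spec.cell_size)
        out_ids.extend(ids[i] for i in members)
    occ = OccurrenceSet.from_arrays(
        np.concatenate(xs), np.concatenate(ys), range_label=name,
        individual_id=np.array(out_ids, dtype=object))
    return occ


@dataclass
class ScenarioData:
    """Everything one synthetic scenario produced, plus the truth."""

    spec: ScenarioSpec
    grids: dict            # range name -> EnvGrid
    occurrences: dict      # range name -> OccurrenceSet
    genotypes: GenotypeMatrix
    q_truth: AncestryMatrix
    allele_freqs_truth: np.ndarray

    @property
    def target_range(self) -> str:
        """The non-equilibrium range the analysis projects into."""
        idx = self.spec.truncated_range
        return self.spec.range_name(idx if idx is not None
                                    else self.spec.n_ranges - 1)

    def all_occurrences(self) -> OccurrenceSet:
        import pandas as pd

        return OccurrenceSet(pd.concat([o.df for o in self.occurrences.values()],
                                       ignore_index=True))


def generate_scenario(spec: ScenarioSpec) -> ScenarioData:
    """Generate the full synthetic study system for a spec."""
    genotypes, q_truth, P = generate_genotypes(spec)
    grids, occs = {}, {}
    for r in range(spec.n_ranges):
        name = spec.range_name(r)
        grid = generate_landscape(spec, r)
        grids[name] = grid
        occs[name] = place_occurrences(spec, grid, q_truth, r,
                                       range_labels=genotypes.range_labels)
    return ScenarioData(spec, grids, occs, genotypes, q_truth, P)
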