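"""Synthetic cohorts of BOLD-like network time series with known ground truth.

Subjects are draws from stable VAR(1) processes on the seven Yeo networks.
Each cohort group has a coupling template — a directed edge set encoding the
qualitative connectivity pattern of one study population — and per-subject
couplings are jittered around the template so that clinical scores can be
linearly coupled (with noise) to a designated connection strength.

The generator targets the statistical structure the downstream analysis
assumes (linear lag-1 directed coupling, slow autocorrelated dynamics,
additive observation noise). It does not model hemodynamic convolution,
scanner drift or motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datatypes import YEO7_CHANNELS, TimeSeriesSet
from .io import save_report, save_timeseries

#: Samples discarded at the start of every simulation (initial-condition transient).
BURN_IN = 50

#: Maximum rejection-sampling retries for a stable jittered coupling matrix.
MAX_STABILITY_RETRIES = 100

# Directed edge sets (source -> target) for the four study populations.
# Qualitative pattern per group: young healthy controls have bidirectional
# control<->somatomotor coupling plus top-down default-mode -> control and
# attention -> limbic influence; older controls lose control<->somatomotor
# and show attention/limbic -> somatomotor and control -> default-mode
# instead; prodromal patients have a secluded somatomotor network (no
# outgoing edges) with attention -> somatomotor/control compensation; in
# manifest disease the somatomotor network re-routes through vision
# (SMN -> VIS appears) while limbic -> somatomotor persists.
TEMPLATE_EDGES: dict[str, tuple[tuple[str, str], ...]] = {
    "young_hc": (
        ("FPN", "SMN"),
        ("SMN", "FPN"),
        ("DMN", "FPN"),
        ("DAN", "LIN"),
        ("VAN", "LIN"),
    ),
    "old_hc": (
        ("DAN", "FPN"),
        ("VAN", "FPN"),
        ("VAN", "SMN"),
        ("LIN", "SMN"),
        ("FPN", "DMN"),
    ),
    "prodromal_pd": (
        ("DAN", "FPN"),
        ("VAN", "FPN"),
        ("DAN", "SMN"),
        ("VAN", "SMN"),
        ("FPN", "DAN"),
        ("FPN", "DMN"),
    ),
    "manifest_pd": (
        ("DAN", "SMN"),
        ("VAN", "SMN"),
        ("LIN", "SMN"),
        ("SMN", "VIS"),
        ("FPN", "DAN"),
        ("FPN", "DMN"),
    ),
}


def spectral_radius(a: np.ndarray) -> float:
    return float(np.abs(np.linalg.eigvals(a)).max())


@dataclass
class CouplingTemplate:
    """Directed lag-1 coupling pattern for one cohort group.

    ``coupling`` is N x N with entry (i, j) = influence of channel j on
    channel i at lag 1; the diagonal holds ``self_coupling``. The template
    must be stable (spectral radius < 1) so the VAR(1) it defines is
    stationary.
    """

    name: str
    coupling: np.ndarray
    self_coupling: float
    channels: tuple[str, ...] = YEO7_CHANNELS

    def __post_init__(self) -> None:
        self.coupling = np.asarray(self.coupling, dtype=float)
        n = len(self.channels)
        if self.coupling.shape != (n, n):
            raise ValueError(f"coupling shape {self.coupling.shape} for {n} channels")
        if not np.allclose(np.diag(self.coupling), self.self_coupling):
            raise ValueError("diagonal entries must equal self_coupling")
        rho = spectral_radius(self.coupling)
        if rho >= 1.0:
            raise ValueError(
                f"unstable template {self.name!r}: spectral radius {rho:.3f} >= 1"
            )

    @property
    def edge_list(self) -> frozenset[tuple[str, str]]:
        """Ordered (source, target) pairs with nonzero off-diagonal coupling."""
        edges = set()
        for i, tgt in enumerate(self.channels):
            for j, src in enumerate(self.channels):
                if i != j and self.coupling[i, j] != 0.0:
                    edges.add((src, tgt))
        return frozenset(edges)

    def adjacency(self) -> np.ndarray:
        """Binary N x N ground-truth adjacency (diagonal zero)."""
        adj = (self.coupling != 0.0).astype(float)
        np.fill_diagonal(adj, 0.0)
        return adj


def make_template(
    name: str,
    base_coupling: float = 0.3,
    self_coupling: float = 0.5,
    edges: tuple[tuple[str, str], ...] | None = None,
    channels: tuple[str, ...] = YEO7_CHANNELS,
) -> CouplingTemplate:
    """Build a stable coupling template for a known group label or custom edges.

    Known labels ('young_hc', 'old_hc', 'prodromal_pd', 'manifest_pd') carry
    documented, pairwise-distinguishable edge sets; 'custom' requires an
    explicit ``edges`` tuple of (source, target) channel-name pairs. Every
    off-diagonal edge gets weight ``base_coupling``; the diagonal gets
    ``self_coupling``.
    """
    if not (np.isfinite(base_coupling) and np.isfinite(self_coupling)):
        raise ValueError("coupling scalars must be finite")
    if edges is None:
        if name not in TEMPLATE_EDGES:
            raise ValueError(
                f"unknown template {name!r} and no custom edges supplied; "
                f"known labels: {sorted(TEMPLATE_EDGES)}"
            )
        edges = TEMPLATE_EDGES[name]
    index = {c: k for k, c in enumerate(channels)}
    coupling = np.eye(len(channels)) * self_coupling
    for src, tgt in edges:
        if src not in index or tgt not in index:
            raise ValueError(f"edge ({src}, {tgt}) names unknown channels")
        if src == tgt:
            raise ValueError(f"self-edge ({src}, {tgt}) not allowed; use self_coupling")
        coupling[index[tgt], index[src]] = base_coupling
    return CouplingTemplate(
        name=name, coupling=coupling, self_coupling=self_coupling, channels=channels
    )


def simulate_subject(
    template: CouplingTemplate,
    n_times: int,
    tr: float = 2.0,
    innovation_sd: float = 1.0,
    observation_noise_sd: float = 0.0,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    subject_id: str = "sim",
    coupling: np.ndarray | None = None,
) -> TimeSeriesSet:
    """Simulate one subject: VAR(1) recursion x_t = C x_{t-1} + e_t.

    Innovations are i.i.d. N(0, innovation_sd^2 I); optional additive white
    observation noise; the first ``BURN_IN`` samples are discarded so the
    returned T samples are draws from the stationary regime. Deterministic
    given the seed. ``coupling`` overrides the template matrix (used for
    per-subject jitter); it must itself be stable.
    """
    if n_times < 50:
        raise ValueError(f"T must be >= 50, got {n_times}")
    if innovation_sd <= 0:
        raise ValueError("innovation_sd must be positive")
    if observation_noise_sd < 0:
        raise ValueError("observation_noise_sd must be nonnegative")
    c = template.coupling if coupling is None else np.asarray(coupling, dtype=float)
    rho = spectral_radius(c)
    if rho >= 1.0:
        raise ValueError(f"unstable coupling matrix: spectral radius {rho:.3f} >= 1")
    rng = np.random.default_rng(seed)
    n = c.shape[0]
    total = n_times + BURN_IN
    innov = rng.normal(0.0, innovation_sd, size=(total, n))
    x = np.zeros((total, n))
    for t in range(1, total):
        x[t] = c @ x[t - 1] + innov[t]
    x = x[BURN_IN:]
    if observation_noise_sd > 0:
        x = x + rng.normal(0.0, observation_noise_sd, size=x.shape)
    return TimeSeriesSet(
        subject_id=subject_id,
        data=x,
        channels=template.channels,
        tr=tr,
        group=template.name,
    )


@dataclass
class ClinicalModel:
    """Linear score model: score = slope * true_coupling(edge) + N(0, noise_sd)."""

    edge: tuple[str, str]  # (source, target)
    score_name: str
    slope: float = 1.0
    noise_sd: float = 0.0


@dataclass
class CohortSpec:
    """Recipe for a synthetic multi-group cohort.

    ``groups`` pairs each coupling template with a subject count.
    ``coupling_jitter_sd`` perturbs each nonzero off-diagonal coupling per
    subject (rejection-sampled until stable), giving the across-subject
    variability that the clinical score models draw their signal from.
    """

    groups: list[tuple[CouplingTemplate, int]]
    n_times: int = 400
    tr: float = 2.0
    coupling_jitter_sd: float = 0.0
    innovation_sd: float = 1.0
    observation_noise_sd: float = 0.0
    clinical_models: list[ClinicalModel] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("cohort needs at least one group")
        for tmpl, n_sub in self.groups:
            if n_sub < 1:
                raise ValueError(f"group {tmpl.name!r} needs n_subjects >= 1")
        if self.n_times < 50:
            raise ValueError("T must be >= 50")
        if self.tr <= 0:
            raise ValueError("TR must be positive")


@dataclass
class SyntheticCohort:
    """Generated cohort with full provenance: per-subject truth and scores."""

    subjects: list[TimeSeriesSet]
    truth_couplings: dict[str, np.ndarray]  # subject_id -> coupling used
    group_edges: dict[str, frozenset[tuple[str, str]]]  # group -> template edges
    clinical_scores: dict[str, dict[str, float]]  # subject_id -> score_name -> value
    spec: CohortSpec

    def group_subjects(self, group: str) -> list[TimeSeriesSet]:
        return [s for s in self.subjects if s.group == group]

    def true_coupling_values(self, edge: tuple[str, str]) -> dict[str, float]:
        """Per-subject true coupling strength on (source, target)."""
        src, tgt = edge
        out = {}
        for sid, c in self.truth_couplings.items():
            ts = next(s for s in self.subjects if s.subject_id == sid)
            i = ts.channels.index(tgt)
            j = ts.channels.index(src)
            out[sid] = float(c[i, j])
        return out


def _jitter_coupling(
    template: CouplingTemplate, jitter_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Perturb nonzero off-diagonal couplings; rejection-sample until stable."""
    base = template.coupling
    if jitter_sd == 0.0:
        return base.copy()
    mask = (base != 0.0) & ~np.eye(base.shape[0], dtype=bool)
    for _ in range(MAX_STABILITY_RETRIES):
        c = base.copy()
        c[mask] += rng.normal(0.0, jitter_sd, size=int(mask.sum()))
        if spectral_radius(c) < 1.0:
            return c
    raise RuntimeError(
        f"no stable jittered coupling for template {template.name!r} after "
        f"{MAX_STABILITY_RETRIES} retries (jitter_sd={jitter_sd})"
    )


def simulate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate all subjects of a cohort spec, recording truth and scores.

    Subjects are independent; per-subject seeds derive deterministically
    from ``spec.seed`` so the whole cohort is reproducible bit-for-bit.
    """
    root = np.random.SeedSequence(spec.seed)
    n_total = sum(n for _, n in spec.groups)
    seqs = root.spawn(n_total + 1)
    score_rng = np.random.default_rng(seqs[-1])

    subjects: list[TimeSeriesSet] = []
    truths: dict[str, np.ndarray] = {}
    scores: dict[str, dict[str, float]] = {}
    group_edges = {tmpl.name: tmpl.edge_list for tmpl, _ in spec.groups}

    k = 0
    for tmpl, n_sub in spec.groups:
        for s in range(n_sub):
            sid = f"{tmpl.name}_{s:03d}"
            sub_rng = np.random.default_rng(seqs[k])
            coupling = _jitter_coupling(tmpl, spec.coupling_jitter_sd, sub_rng)
            ts = simulate_subject(
                tmpl,
                spec.n_times,
                tr=spec.tr,
                innovation_sd=spec.innovation_sd,
                observation_noise_sd=spec.observation_noise_sd,
                seed=sub_rng,
                subject_id=sid,
                coupling=coupling,
            )
            subjects.append(ts)
            truths[sid] = coupling
            scores[sid] = {}
            index = {c: m for m, c in enumerate(tmpl.channels)}
            for cm in spec.clinical_models:
                src, tgt = cm.edge
                true_val = coupling[index[tgt], index[src]]
                noise = score_rng.normal(0.0, cm.noise_sd) if cm.noise_sd > 0 else 0.0
                scores[sid][cm.score_name] = float(cm.slope * true_val + noise)
            k += 1

    return SyntheticCohort(
        subjects=subjects,
        truth_couplings=truths,
        group_edges=group_edges,
        clinical_scores=scores,
        spec=spec,
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write per-subject TSV series plus sidecar JSON provenance files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for ts in cohort.subjects:
        save_timeseries(ts, outdir / f"{ts.subject_id}.tsv")
        sidecar = {
            "subject_id": ts.subject_id,
            "group": ts.group,
            "tr": ts.tr,
            "channels": list(ts.channels),
            "truth_coupling": cohort.truth_couplings[ts.subject_id],
            "truth_edges": sorted(
                list(e) for e in cohort.group_edges.get(ts.group, frozenset())
            ),
            "clinical_scores": cohort.clinical_scores.get(ts.subject_id, {}),
        }
        save_report(sidecar, outdir / f"{ts.subject_id}.json")
    return outdir
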