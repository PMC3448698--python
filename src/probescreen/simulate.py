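"""Synthetic probe-level microarray data with known ground truth.

Emulates the structure of a FACS-sorted retinal endothelial-cell screen on
oligonucleotide arrays: four sample populations (whole P8 retina, GFP− P8
cells, GFP+ P8 endothelial cells, GFP+ adult endothelial cells) with three
replicate arrays each, probe sets of ~16 member probes following the
multiplicative (rank-one) intensity model PM_ij = θ_i·φ_j + ε_ij, a minority
of probe sets truly up-regulated in a target population, and a minority of
internally inconsistent probe sets whose discordant member probes track an
independent expression profile.

Every dataset is emitted together with a :class:`SyntheticTruth` sidecar so
that downstream stages (expression-index fitting, the SAM screen, the
probe-consistency filter, the keyword filter) can be validated against known
labels without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import AnnotationTable
from .containers import ProbeLevelMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_dataset",
    "generate_annotations",
    "write_truth",
    "read_truth",
    "DEFAULT_GROUPS",
    "DEFAULT_TARGET_GROUP",
    "DEFAULT_GO_VOCABULARY",
    "GTP_TERMS",
]

#: Study design: 4 sample populations × 3 replicate arrays.
DEFAULT_GROUPS: tuple = (
    ("retina_P8", 3),
    ("GFPneg_P8", 3),
    ("GFPpos_P8", 3),
    ("GFPpos_adult", 3),
)

#: Population in which truly differential probe sets are up-regulated.
DEFAULT_TARGET_GROUP = "GFPpos_P8"

#: The GTP-related gene-ontology terms the keyword filter must recognise.
GTP_TERMS = (
    "GTP binding",
    "GTPase activity",
    "GTPase activator activity",
    "small GTPase regulator activity",
    "small GTPase mediated signal transduction",
)

#: Small mixed vocabulary for annotation simulation: the GTP terms plus
#: generic terms that must NOT match the 'GTP' keyword.
DEFAULT_GO_VOCABULARY = GTP_TERMS + (
    "ATP binding",
    "protein binding",
    "DNA binding",
    "transcription factor activity",
    "cell migration",
    "cell motility",
    "angiogenesis",
    "signal transduction",
    "kinase activity",
    "membrane",
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic probe-level dataset.

    Defaults mirror the screen design the generator emulates: 4 populations
    × 3 replicates, 16 probes per set, ~4.4% of probe sets truly up in the
    GFP+ P8 population at 3-fold, 5% internally inconsistent sets with half
    of their probes discordant, additive Gaussian noise at 10% of the
    probe-set signal scale, and log-normal baselines (ln-mean 6, ln-sd 1,
    i.e. a median intensity around 400).
    """

    n_probesets: int = 1000
    probes_per_set: int = 16
    groups: tuple = DEFAULT_GROUPS
    target_group: str = DEFAULT_TARGET_GROUP
    de_fraction: float = 1623 / 36701
    de_fold: float = 3.0
    inconsistent_fraction: float = 0.05
    discordant_probe_fraction: float = 0.5
    noise_sd: float = 0.1
    baseline_mean: float = 6.0
    baseline_sd: float = 1.0
    intensity_floor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probesets < 1:
            raise ValueError("n_probesets must be positive")
        if self.probes_per_set < 2:
            raise ValueError("probes_per_set must be >= 2")
        for frac_name in ("de_fraction", "inconsistent_fraction", "discordant_probe_fraction"):
            value = getattr(self, frac_name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{frac_name} must be in [0, 1], got {value}")
        if self.de_fraction + self.inconsistent_fraction > 1.0:
            raise ValueError(
                "de_fraction + inconsistent_fraction must be <= 1 "
                "(differential and inconsistent classes are disjoint)"
            )
        if self.de_fold <= 1.0:
            raise ValueError("de_fold must be > 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        self.groups = tuple((str(label), int(n)) for label, n in self.groups)
        if any(n < 2 for _, n in self.groups):
            raise ValueError("every group needs >= 2 replicates")
        labels = [label for label, _ in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")
        if self.target_group not in labels:
            raise ValueError(f"target_group {self.target_group!r} not among group labels")

    # -- derived layout ---------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return [f"{label}_{r + 1}" for label, n in self.groups for r in range(n)]

    @property
    def sample_group_labels(self) -> list:
        return [label for label, n in self.groups for _ in range(n)]

    @property
    def n_samples(self) -> int:
        return sum(n for _, n in self.groups)


@dataclass
class SyntheticTruth:
    """Ground-truth labels emitted alongside every simulated dataset.

    ``table`` has one row per probe set with columns ``is_de``,
    ``true_fold`` (1.0 unless truly differential) and ``is_inconsistent``;
    ``discordant_probes`` maps each inconsistent probe set to its discordant
    probe ids (empty for consistent sets). ``theta``/``phi`` are the
    noise-free model parameters, the oracle for expression-index recovery.
    """

    table: pd.DataFrame
    discordant_probes: dict = field(default_factory=dict)
    theta: pd.DataFrame = None
    phi: pd.Series = None
    target_group: str = DEFAULT_TARGET_GROUP

    @property
    def probeset_ids(self) -> pd.Index:
        return self.table.index

    @property
    def de_ids(self) -> list:
        return list(self.table.index[self.table["is_de"]])

    @property
    def inconsistent_ids(self) -> list:
        return list(self.table.index[self.table["is_inconsistent"]])


def generate_dataset(config: SimulationConfig) -> tuple[ProbeLevelMatrix, SyntheticTruth]:
    """Simulate one probe-level dataset plus its ground truth.

    For a consistent probe set g the intensity is θ(g,s)·φ(g,j) + ε with
    ε ~ N(0, noise_sd·scale_g), where scale_g is the set's baseline θ. θ is
    constant across all samples except for truly differential sets, whose
    θ in the target group is multiplied by ``de_fold``. φ is drawn positive
    (log-normal) and rescaled so Σ_j φ_j² = J. In an inconsistent set, a
    fraction of probes instead follows an independently drawn group-level
    profile θ′. Intensities are floored at ``intensity_floor``.

    Bit-identical output under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    G, J, S = config.n_probesets, config.probes_per_set, config.n_samples
    group_labels = np.asarray(config.sample_group_labels)
    target_mask = group_labels == config.target_group

    probeset_ids = pd.Index([f"ps{g + 1:05d}" for g in range(G)], name="probeset_id")
    probe_ids = pd.Index(
        [f"ps{g + 1:05d}_p{j + 1:02d}" for g in range(G) for j in range(J)],
        name="probe_id",
    )
    sample_ids = pd.Index(config.sample_ids, name="sample_id")

    # class assignment: DE and inconsistent sets are disjoint
    n_de = int(round(config.de_fraction * G))
    n_inc = int(round(config.inconsistent_fraction * G))
    n_inc = min(n_inc, G - n_de)
    order = rng.permutation(G)
    de_idx = np.sort(order[:n_de])
    inc_idx = np.sort(order[n_de:n_de + n_inc])
    is_de = np.zeros(G, dtype=bool)
    is_de[de_idx] = True
    is_inc = np.zeros(G, dtype=bool)
    is_inc[inc_idx] = True

    # noise-free model parameters
    baseline = np.exp(rng.normal(config.baseline_mean, config.baseline_sd, size=G))
    theta = np.tile(baseline[:, None], (1, S))
    theta[np.ix_(is_de, target_mask)] *= config.de_fold

    phi = np.exp(rng.normal(0.0, 0.4, size=(G, J)))
    phi *= np.sqrt(J / (phi ** 2).sum(axis=1, keepdims=True))

    signal = theta[:, None, :] * phi[:, :, None]          # (G, J, S)
    noise_scale = config.noise_sd * baseline
    intensities = signal + rng.normal(0.0, 1.0, size=(G, J, S)) * noise_scale[:, None, None]

    # inconsistent sets: discordant probes track an independent group profile
    discordant: dict = {}
    n_disc = max(1, int(round(config.discordant_probe_fraction * J))) if n_inc else 0
    group_sizes = [n for _, n in config.groups]
    for g in inc_idx:
        probes = rng.choice(J, size=n_disc, replace=False)
        probes.sort()
        levels = np.exp(rng.normal(config.baseline_mean, config.baseline_sd, size=len(group_sizes)))
        theta_alt = np.repeat(levels, group_sizes)         # constant within group
        alt_signal = theta_alt[None, :] * phi[g, probes, None]
        alt_noise = rng.normal(0.0, 1.0, size=(len(probes), S)) * noise_scale[g]
        intensities[g, probes, :] = alt_signal + alt_noise
        discordant[probeset_ids[g]] = {f"{probeset_ids[g]}_p{j + 1:02d}" for j in probes}

    np.maximum(intensities, config.intensity_floor, out=intensities)

    data = ProbeLevelMatrix(
        intensities=pd.DataFrame(
            intensities.reshape(G * J, S), index=probe_ids, columns=sample_ids
        ),
        probe_map=pd.Series(np.repeat(probeset_ids.values, J), index=probe_ids, name="probeset_id"),
        sample_groups=pd.Series(group_labels, index=sample_ids, name="group"),
    )
    truth = SyntheticTruth(
        table=pd.DataFrame(
            {
                "is_de": is_de,
                "true_fold": np.where(is_de, config.de_fold, 1.0),
                "is_inconsistent": is_inc,
            },
            index=probeset_ids,
        ),
        discordant_probes=discordant,
        theta=pd.DataFrame(theta, index=probeset_ids, columns=sample_ids),
        phi=pd.Series(phi.reshape(-1), index=probe_ids, name="phi"),
        target_group=config.target_group,
    )
    return data, truth


def generate_annotations(
    truth,
    term_vocabulary=DEFAULT_GO_VOCABULARY,
    tagged_fraction: float = 96 / 1623,
    seed: int = 0,
    max_terms: int = 3,
    keyword: str = "GTP",
) -> AnnotationTable:
    """Simulate a probe-set → GO-term annotation table.

    Each probe set receives 0..``max_terms`` terms. An independent
    Bernoulli(``tagged_fraction``) draw decides whether a set carries at
    least one term containing ``keyword``; the tagged ids are recorded on
    the returned table (``tagged_ids``). Untagged sets draw only from the
    non-keyword part of the vocabulary (and may end up with zero terms).
    """
    if not term_vocabulary:
        raise ValueError("term vocabulary must be non-empty")
    if not 0.0 <= tagged_fraction <= 1.0:
        raise ValueError("tagged_fraction must be in [0, 1]")
    ids = list(truth.probeset_ids) if hasattr(truth, "probeset_ids") else list(truth)
    vocab = list(term_vocabulary)
    kw_terms = [t for t in vocab if keyword in t]
    plain_terms = [t for t in vocab if keyword not in t]
    if tagged_fraction > 0 and not kw_terms:
        raise ValueError(f"vocabulary has no term containing {keyword!r}")

    rng = np.random.default_rng(seed)
    tagged = rng.random(len(ids)) < tagged_fraction
    terms: dict = {}
    tagged_ids = []
    for probeset_id, is_tagged in zip(ids, tagged):
        assigned: set = set()
        if is_tagged:
            n_kw = rng.integers(1, min(2, len(kw_terms)) + 1)
            assigned.update(rng.choice(kw_terms, size=n_kw, replace=False))
            tagged_ids.append(probeset_id)
        if plain_terms:
            n_plain = rng.integers(0, max_terms + 1)
            n_plain = min(n_plain, len(plain_terms))
            if n_plain:
                assigned.update(rng.choice(plain_terms, size=n_plain, replace=False))
        if assigned:
            terms[probeset_id] = assigned
    return AnnotationTable(terms, tagged_ids=tagged_ids)


def write_truth(truth: SyntheticTruth, path) -> None:
    out = truth.table.copy()
    out["discordant_probe_ids"] = [
        ";".join(sorted(truth.discordant_probes.get(g, ()))) for g in out.index
    ]
    out.to_csv(path, sep="\t")


def read_truth(path) -> SyntheticTruth:
    table = pd.read_csv(path, sep="\t", index_col=0)
    disc = {}
    if "discordant_probe_ids" in table.columns:
        raw = table.pop("discordant_probe_ids").fillna("")
        disc = {g: set(v.split(";")) for g, v in raw.items() if v}
    table["is_de"] = table["is_de"].astype(bool)
    table["is_inconsistent"] = table["is_inconsistent"].astype(bool)
    return SyntheticTruth(table=table, discordant_probes=disc)
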