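"""Synthetic study generator for the mint allelopathy screen.

Generates every input the analysis pipeline consumes — aligned barcode
sequences with planted mislabels, per-accession GC peak tables with a
planted active compound, germination count tables, Evans-Blue mortality
count tables, and AO/EB per-nucleus intensity tables — together with a
ground-truth sidecar so that every downstream estimate has a
parameter-recovery test.

The shipped :func:`paper_scenario` encodes, as true probabilities, the
study conditions of the screen this package models: 100 cress seeds x 3
replicates per germination condition, 600 cells x 3 replicates per
mortality condition, ~275 nuclei x 2 series per AO/EB condition, a
menthone/isomenthone-rich pair of accession groups, and a tubulin marker
line whose menthone/isomenthone EC50 sits 4-fold below the wild type.

Randomness is split into one independent stream per output table (seeded
from ``rng_seed`` plus a per-table tag), so generating one table never
perturbs another.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .barcoding import NUCLEOTIDES, PhyloTree, SequenceRecord, TreeNode, write_fasta

# stream tags: one RNG stream per table
_TAGS = {
    "sequences": 1,
    "oil_profiles": 2,
    "germination": 3,
    "mortality": 4,
    "nuclei": 5,
}

WT = "WT"
ACTIN_LINE = "actin-marker"
TUBULIN_LINE = "tubulin-marker"
CELL_LINES = (WT, ACTIN_LINE, TUBULIN_LINE)


def _rng(seed: int, table: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _TAGS[table]])


def loglogistic(dose: float, ec50: float, slope: float) -> float:
    """Two-parameter log-logistic response rising from 0 to 1."""
    return 1.0 / (1.0 + (ec50 / dose) ** slope) if dose > 0 else 0.0


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------

class ConfigurationError(ValueError):
    pass


@dataclass
class ScenarioConfig:
    """Full description of a synthetic study.

    Probabilities are true event probabilities in [0, 1]; doses are nominal
    labels (ppm for germination, % v/v for cytotoxicity) and are never
    converted between unit systems.
    """

    species_map: dict[str, str]  # accession -> true species
    outgroup: str  # accession id of the outgroup
    compounds: list[str]  # post-pooling compound vocabulary
    active_compound: str
    mislabel_pairs: list[tuple[str, str]] = field(default_factory=list)
    doses: list[float] = field(default_factory=lambda: [0.01, 0.1, 1.0])
    true_inhibition: dict[tuple[str, float], float] = field(default_factory=dict)
    true_oil_inhibition: dict[str, float] = field(default_factory=dict)
    oil_dose: float = 0.1
    true_mortality: dict[tuple[str, str, float, float], float] = field(
        default_factory=dict
    )
    true_ec50: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=dict
    )  # (compound, line) -> (ec50, slope)
    mortality_doses: list[float] = field(default_factory=list)
    oil_profiles: dict[str, dict[str, float]] = field(default_factory=dict)
    unidentified_fraction: dict[str, float] = field(default_factory=dict)
    isomer_split: dict[str, dict[str, float]] = field(default_factory=dict)
    solvent_map: dict[str, str] = field(default_factory=dict)
    nucleus_truth: dict[tuple[str, float], float] = field(default_factory=dict)
    rich_accessions: list[str] = field(default_factory=list)
    seeds_per_box: int = 100
    replicates: int = 3
    cells_scored: int = 600
    nuclei_per_series: int = 275
    n_series: int = 2
    p_control: float = 0.95
    dirichlet_concentration: float = 300.0
    nucleus_beta_concentration: float = 20.0
    seq_length: int = 600
    mutation_rate: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.species_map) < 2:
            raise ConfigurationError("need at least 2 accessions")
        if self.active_compound not in self.compounds:
            raise ConfigurationError(
                f"active compound {self.active_compound!r} not in compound list"
            )
        for a, b in self.mislabel_pairs:
            for acc in (a, b):
                if acc not in self.species_map:
                    raise ConfigurationError(
                        f"mislabel pair references unknown accession {acc!r}"
                    )
        for name, probs in (
            ("true_inhibition", self.true_inhibition.values()),
            ("true_oil_inhibition", self.true_oil_inhibition.values()),
            ("true_mortality", self.true_mortality.values()),
            ("nucleus_truth", self.nucleus_truth.values()),
            ("p_control", [self.p_control]),
        ):
            for p in probs:
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(f"{name} probability {p} outside [0,1]")

    @property
    def accessions(self) -> list[str]:
        return list(self.species_map)

    @property
    def n_accessions(self) -> int:
        return len(self.species_map)


@dataclass
class Accession:
    id: str
    true_species: str
    declared_species: str


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    true_tree_newick: str
    true_labels: dict[str, str]
    declared_labels: dict[str, str]
    planted_mislabels: list[str]
    active_compound: str
    true_inhibition: dict[str, float]  # "treatment@dose" -> p
    true_oil_inhibition: dict[str, float]
    true_mortality: dict[str, float]  # "compound|line|dose|time" -> p
    true_ec50: dict[str, float]  # "compound|line" -> ec50

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def build_ground_truth(config: ScenarioConfig, tree: PhyloTree) -> GroundTruth:
    panel = generate_accession_panel(config)
    return GroundTruth(
        true_tree_newick=tree.to_newick(with_support=False),
        true_labels={a.id: a.true_species for a in panel},
        declared_labels={a.id: a.declared_species for a in panel},
        planted_mislabels=sorted(
            {acc for pair in config.mislabel_pairs for acc in pair}
        ),
        active_compound=config.active_compound,
        true_inhibition={
            f"{t}@{d:g}": p for (t, d), p in config.true_inhibition.items()
        },
        true_oil_inhibition=dict(config.true_oil_inhibition),
        true_mortality={
            f"{c}|{l}|{d:g}|{t:g}": p
            for (c, l, d, t), p in config.true_mortality.items()
        },
        true_ec50={f"{c}|{l}": e for (c, l), (e, _s) in config.true_ec50.items()},
    )


# ---------------------------------------------------------------------------
# the default scenario
# ---------------------------------------------------------------------------

def paper_scenario(rng_seed: int = 0) -> ScenarioConfig:
    """The shipped default study: a reconstruction of the screen's narrated
    conditions, encoded as true probabilities. It is data, not code."""
    species_map = {
        "ACC01": "Mentha spicata",
        "ACC02": "Mentha spicata",
        "ACC03": "Mentha spicata",
        "ACC04": "Mentha longifolia",
        "ACC05": "Mentha longifolia",
        "ACC06": "Mentha longifolia",
        "ACC07": "Agastache rugosa",
        "ACC08": "Agastache rugosa",
        "ACC09": "Agastache rugosa",
        "ACC10": "Melissa officinalis",
    }
    active = "menthone/isomenthone"
    compounds = [
        active, "menthol", "limonene", "pulegone",
        "carvone", "linalool", "citral", "1,8-cineole",
    ]
    # mean relative peak areas (%) per species, post-pooling vocabulary
    oil_profiles = {
        "Mentha spicata": {
            active: 1.5, "menthol": 1.0, "limonene": 8.0, "pulegone": 0.5,
            "carvone": 45.0, "linalool": 2.0, "citral": 2.0, "1,8-cineole": 5.0,
        },
        "Mentha longifolia": {
            active: 30.0, "menthol": 35.0, "limonene": 3.0, "pulegone": 2.0,
            "carvone": 2.0, "linalool": 3.0, "citral": 2.0, "1,8-cineole": 8.0,
        },
        "Agastache rugosa": {
            active: 32.0, "menthol": 1.0, "limonene": 10.0, "pulegone": 8.0,
            "carvone": 1.0, "linalool": 4.0, "citral": 2.0, "1,8-cineole": 12.0,
        },
        "Melissa officinalis": {
            active: 0.0, "menthol": 0.5, "limonene": 2.0, "pulegone": 0.0,
            "carvone": 0.5, "linalool": 5.0, "citral": 30.0, "1,8-cineole": 2.0,
        },
    }
    unidentified = {
        sp: 100.0 - sum(prof.values()) for sp, prof in oil_profiles.items()
    }
    doses = [0.01, 0.1, 1.0]
    true_inhibition = {
        (active, 0.01): 0.70, (active, 0.1): 0.80, (active, 1.0): 0.99,
        ("menthol", 0.01): 0.30, ("menthol", 0.1): 0.40, ("menthol", 1.0): 0.95,
        ("linalool", 0.01): 0.30, ("linalool", 0.1): 0.35, ("linalool", 1.0): 0.95,
        ("limonene", 0.01): 0.05, ("limonene", 0.1): 0.10, ("limonene", 1.0): 0.20,
    }
    true_oil_inhibition = {
        "ACC01": 0.25, "ACC02": 0.25, "ACC03": 0.25,
        "ACC04": 0.80, "ACC05": 0.80, "ACC06": 0.80,
        "ACC07": 0.85, "ACC08": 0.85, "ACC09": 0.85,
        "ACC10": 0.05,
    }
    # cytotoxicity: 2-parameter log-logistic in dose (% v/v), slope 3;
    # tubulin line 4-fold more sensitive, actin line mildly so
    ec50_wt, slope = 0.08, 3.0
    true_ec50 = {
        (active, WT): (ec50_wt, slope),
        (active, ACTIN_LINE): (ec50_wt / 1.6, slope),
        (active, TUBULIN_LINE): (ec50_wt / 4.0, slope),
    }
    mortality_doses = [0.0125, 0.025, 0.05, 0.1, 0.2, 0.4]
    working_dose = 0.2
    true_mortality: dict[tuple[str, str, float, float], float] = {}
    # dose series at 15 min for the active compound, per line
    for line in CELL_LINES:
        e, s = true_ec50[(active, line)]
        for d in mortality_doses:
            true_mortality[(active, line, d, 15.0)] = loglogistic(d, e, s)
    # time courses at the working dose for the other compounds
    time_course = {
        ("menthol", WT): (0.25, 0.65),
        ("menthol", ACTIN_LINE): (0.30, 0.70),
        ("menthol", TUBULIN_LINE): (0.45, 0.90),
        ("limonene", WT): (0.10, 0.20),
        ("limonene", ACTIN_LINE): (0.10, 0.20),
        ("limonene", TUBULIN_LINE): (0.12, 0.22),
        ("control:ethanol", WT): (0.02, 0.03),
        ("control:ethanol", ACTIN_LINE): (0.02, 0.03),
        ("control:ethanol", TUBULIN_LINE): (0.02, 0.03),
        ("control:n-hexane", WT): (0.02, 0.03),
        ("control:n-hexane", ACTIN_LINE): (0.02, 0.03),
        ("control:n-hexane", TUBULIN_LINE): (0.02, 0.03),
    }
    for (compound, line), (p15, p30) in time_course.items():
        true_mortality[(compound, line, working_dose, 15.0)] = p15
        true_mortality[(compound, line, working_dose, 30.0)] = p30
    # the active compound's 30-min point continues its saturation course
    for line in CELL_LINES:
        e, s = true_ec50[(active, line)]
        p15 = loglogistic(working_dose, e, s)
        true_mortality[(active, line, working_dose, 30.0)] = min(
            1.0, p15 + 0.6 * (1.0 - p15)
        )
    # AO/EB mean red fraction per (compound, dose)
    nucleus_truth: dict[tuple[str, float], float] = {}
    for d in [0.0, 0.0625, 0.125, 0.25, 0.5]:
        nucleus_truth[(active, d)] = 0.05 + 0.90 * loglogistic(d, ec50_wt, slope)
        nucleus_truth[("limonene", d)] = 0.05 + 0.90 * loglogistic(d, 0.6, 2.0)
    solvent_map = {
        active: "control:n-hexane",
        "limonene": "control:n-hexane",
        "linalool": "control:n-hexane",
        "menthol": "control:ethanol",  # menthol is dissolved in ethanol
    }
    for acc in species_map:
        solvent_map[f"oil:{acc}"] = "control:n-hexane"
    return ScenarioConfig(
        species_map=species_map,
        outgroup="ACC10",
        compounds=compounds,
        active_compound=active,
        mislabel_pairs=[("ACC03", "ACC06")],
        doses=doses,
        true_inhibition=true_inhibition,
        true_oil_inhibition=true_oil_inhibition,
        oil_dose=0.1,
        true_mortality=true_mortality,
        true_ec50=true_ec50,
        mortality_doses=mortality_doses,
        oil_profiles=oil_profiles,
        unidentified_fraction=unidentified,
        isomer_split={
            active: {"menthone": 0.75, "isomenthone": 0.25},
            "citral": {"alpha-citral": 0.5, "beta-citral": 0.5},
        },
        solvent_map=solvent_map,
        nucleus_truth=nucleus_truth,
        rng_seed=rng_seed,
    )


# ---------------------------------------------------------------------------
# accession panel and marker sequences
# ---------------------------------------------------------------------------

def generate_accession_panel(config: ScenarioConfig) -> list[Accession]:
    """Accessions with true species and (possibly swapped) declared labels."""
    declared = {acc: sp for acc, sp in config.species_map.items()}
    for a, b in config.mislabel_pairs:
        declared[a], declared[b] = declared[b], declared[a]
    return [
        Accession(acc, config.species_map[acc], declared[acc])
        for acc in config.species_map
    ]


def species_tree(config: ScenarioConfig) -> PhyloTree:
    """The true phylogeny: one clade per species, outgroup on a long stem.

    Branch lengths are expected substitutions per site; within-species
    pendant edges are short relative to between-species stems so that
    inter-species distances dominate intra-species ones.
    """
    by_species: dict[str, list[str]] = {}
    for acc, sp in config.species_map.items():
        by_species.setdefault(sp, []).append(acc)
    outgroup_sp = config.species_map[config.outgroup]
    clades = []
    for sp, accs in by_species.items():
        if sp == outgroup_sp and len(accs) == 1:
            clades.append(TreeNode(accs[0], 0.10))
            continue
        leaves = [TreeNode(acc, 0.004) for acc in accs]
        if len(leaves) == 1:
            leaves[0].branch_length = 0.03
            clades.append(leaves[0])
        else:
            clades.append(TreeNode("", 0.03, None, leaves))
    root = TreeNode("", 0.0, None, clades)
    return PhyloTree(root, rooted=False)


_JC_OTHERS = {b: [c for c in NUCLEOTIDES if c != b] for b in NUCLEOTIDES}


def generate_marker_sequences(
    panel: list[Accession],
    true_tree: PhyloTree,
    seq_length: int = 600,
    mutation_rate: float = 1.0,
    rng_seed: int = 0,
) -> list[SequenceRecord]:
    """Evolve aligned sequences along ``true_tree`` under Jukes-Cantor.

    Each branch of length *b* (times ``mutation_rate``) substitutes a site
    with probability ``3/4 * (1 - exp(-4 b / 3))``, the JC69 site-change
    probability; substitutions pick uniformly among the three other bases.
    """
    if seq_length < 1:
        raise ValueError("seq_length must be >= 1")
    tree_leaves = set(true_tree.leaf_names)
    panel_ids = {a.id for a in panel}
    if tree_leaves != panel_ids:
        raise ValueError(
            f"tree leaves and panel accessions differ: "
            f"{sorted(tree_leaves ^ panel_ids)}"
        )
    rng = _rng(rng_seed, "sequences")
    declared = {a.id: a.declared_species for a in panel}
    root_seq = rng.choice(list(NUCLEOTIDES), size=seq_length)

    out: dict[str, str] = {}

    def evolve(node: TreeNode, parent_seq: np.ndarray) -> None:
        b = node.branch_length * mutation_rate
        p_change = 0.75 * (1.0 - np.exp(-4.0 * b / 3.0))
        seq = parent_seq.copy()
        if p_change > 0:
            hit = rng.random(seq_length) < p_change
            for i in np.flatnonzero(hit):
                seq[i] = rng.choice(_JC_OTHERS[seq[i]])
        if node.is_leaf:
            out[node.name] = "".join(seq)
        else:
            for c in node.children:
                evolve(c, seq)

    for child in true_tree.root.children:
        evolve(child, root_seq)
    if not true_tree.root.children:  # degenerate single-node tree
        out[true_tree.root.name] = "".join(root_seq)
    return [SequenceRecord(a.id, out[a.id], declared[a.id]) for a in panel]


# ---------------------------------------------------------------------------
# oil profiles
# ---------------------------------------------------------------------------

def generate_oil_profiles(
    panel: list[Accession], config: ScenarioConfig
) -> pd.DataFrame:
    """Per-accession GC peak tables as one long DataFrame.

    Compositions are drawn per accession from a Dirichlet centred on the
    species' mean profile, including an "unidentified" fraction that is then
    dropped, so identified peak areas sum to < 100 as in real GC tables.
    Pooled vocabulary entries with a configured isomer split are emitted as
    their member peaks (fixed ratios), leaving the re-pooling to the
    chemistry stage.

    Columns: accession, compound, area.
    """
    if not config.compounds:
        raise ConfigurationError("compound list is empty")
    rng = _rng(config.rng_seed, "oil_profiles")
    rows = []
    for acc in panel:
        prof = config.oil_profiles[acc.true_species]
        unid = config.unidentified_fraction.get(acc.true_species, 0.0)
        names = list(prof) + ["__unidentified__"]
        means = np.array([prof[c] for c in prof] + [unid], dtype=float)
        if means.sum() <= 0:
            raise ConfigurationError(f"empty profile for {acc.true_species}")
        alpha = config.dirichlet_concentration * means / means.sum()
        # Dirichlet with zero-mean components: draw only over positive ones
        pos = alpha > 0
        draw = np.zeros_like(means)
        draw[pos] = rng.dirichlet(alpha[pos])
        areas = 100.0 * draw
        for name, area in zip(names, areas):
            if name == "__unidentified__" or area == 0.0:
                continue
            split = config.isomer_split.get(name)
            if split:
                for member, frac in split.items():
                    rows.append((acc.id, member, area * frac))
            else:
                rows.append((acc.id, name, area))
    return pd.DataFrame(rows, columns=["accession", "compound", "area"])


# ---------------------------------------------------------------------------
# germination counts
# ---------------------------------------------------------------------------

def generate_germination_counts(config: ScenarioConfig) -> pd.DataFrame:
    """Binomial germination counts for compounds, oils, and controls.

    Germinated ~ Binomial(seeds_per_box, p_control * (1 - inhibition));
    control rows carry inhibition 0. Columns: treatment, dose, replicate,
    sown, germinated, control (the name of the matching solvent control).
    """
    rng = _rng(config.rng_seed, "germination")
    conditions: list[tuple[str, float, float, str]] = []
    for (treatment, dose), inh in sorted(config.true_inhibition.items()):
        conditions.append(
            (treatment, dose, inh, config.solvent_map.get(treatment, "control:water"))
        )
    for acc, inh in sorted(config.true_oil_inhibition.items()):
        treatment = f"oil:{acc}"
        conditions.append(
            (treatment, config.oil_dose, inh,
             config.solvent_map.get(treatment, "control:water"))
        )
    controls = sorted({ctrl for *_rest, ctrl in conditions})
    for ctrl in controls:
        conditions.append((ctrl, config.oil_dose, 0.0, ""))

    rows = []
    for treatment, dose, inh, ctrl in conditions:
        p = config.p_control * (1.0 - inh)
        if not 0.0 <= p <= 1.0:
            raise ConfigurationError(f"germination probability {p} outside [0,1]")
        for rep in range(1, config.replicates + 1):
            g = int(rng.binomial(config.seeds_per_box, p))
            rows.append((treatment, dose, rep, config.seeds_per_box, g, ctrl))
    return pd.DataFrame(
        rows, columns=["treatment", "dose", "replicate", "sown", "germinated",
                       "control"]
    )


# ---------------------------------------------------------------------------
# cytotoxicity counts
# ---------------------------------------------------------------------------

def generate_cytotoxicity_counts(config: ScenarioConfig) -> pd.DataFrame:
    """Binomial Evans-Blue counts: stained ~ Binomial(cells_scored, p_dead).

    Columns: compound, line, dose, time, replicate, scored, stained.
    """
    rng = _rng(config.rng_seed, "mortality")
    rows = []
    for (compound, line, dose, time), p in sorted(config.true_mortality.items()):
        if not 0.0 <= p <= 1.0:
            raise ConfigurationError(f"mortality probability {p} outside [0,1]")
        for rep in range(1, config.replicates + 1):
            s = int(rng.binomial(config.cells_scored, p))
            rows.append((compound, line, dose, time, rep, config.cells_scored, s))
    return pd.DataFrame(
        rows,
        columns=["compound", "line", "dose", "time", "replicate", "scored",
                 "stained"],
    )


# ---------------------------------------------------------------------------
# nucleus intensities
# ---------------------------------------------------------------------------

def generate_nucleus_intensities(config: ScenarioConfig) -> pd.DataFrame:
    """Per-nucleus green/red fluorescence intensities for the AO/EB assay.

    Each nucleus gets a total intensity T ~ Gamma(5, 200) split into red and
    green by a Beta-distributed red fraction whose mean rises with dose for
    permeabilizing compounds; the mean ratio is therefore non-decreasing in
    dose by construction. Columns: compound, dose, series, green, red.
    """
    if not config.nucleus_truth:
        raise ConfigurationError("nucleus_truth is empty")
    rng = _rng(config.rng_seed, "nuclei")
    kappa = config.nucleus_beta_concentration
    rows = []
    for (compound, dose), m in sorted(config.nucleus_truth.items()):
        m = min(max(m, 1e-6), 1.0 - 1e-6)
        for series in range(1, config.n_series + 1):
            n = config.nuclei_per_series
            total = rng.gamma(shape=5.0, scale=200.0, size=n)
            ratio = rng.beta(kappa * m, kappa * (1.0 - m), size=n)
            for t, r in zip(total, ratio):
                rows.append((compound, dose, series, t * (1.0 - r), t * r))
    return pd.DataFrame(rows, columns=["compound", "dose", "series", "green", "red"])


# ---------------------------------------------------------------------------
# whole-study export
# ---------------------------------------------------------------------------

def generate_study(config: ScenarioConfig, outdir) -> dict[str, Path]:
    """Generate every table of a study and write it under ``outdir``.

    Writes: sequences.fasta, labels.csv, true_tree.nwk, peaks/<acc>.csv,
    germination.csv, mortality.csv, nuclei.csv, ground_truth.json. Returns
    the path of each artifact.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = generate_accession_panel(config)
    tree = species_tree(config)
    seqs = generate_marker_sequences(
        panel, tree, config.seq_length, config.mutation_rate, config.rng_seed
    )
    paths = {}
    paths["sequences"] = outdir / "sequences.fasta"
    write_fasta(seqs, paths["sequences"])
    paths["labels"] = outdir / "labels.csv"
    pd.DataFrame(
        [(a.id, a.declared_species) for a in panel],
        columns=["accession", "declared_taxon"],
    ).to_csv(paths["labels"], index=False)
    paths["true_tree"] = outdir / "true_tree.nwk"
    paths["true_tree"].write_text(tree.to_newick(with_support=False) + "\n")

    profiles = generate_oil_profiles(panel, config)
    peak_dir = outdir / "peaks"
    peak_dir.mkdir(exist_ok=True)
    for acc, sub in profiles.groupby("accession", sort=True):
        sub[["compound", "area"]].to_csv(peak_dir / f"{acc}.csv", index=False)
    paths["peaks"] = peak_dir

    paths["germination"] = outdir / "germination.csv"
    generate_germination_counts(config).to_csv(paths["germination"], index=False)
    paths["mortality"] = outdir / "mortality.csv"
    generate_cytotoxicity_counts(config).to_csv(paths["mortality"], index=False)
    paths["nuclei"] = outdir / "nuclei.csv"
    generate_nucleus_intensities(config).to_csv(paths["nuclei"], index=False)

    paths["ground_truth"] = outdir / "ground_truth.json"
    paths["ground_truth"].write_text(build_ground_truth(config, tree).to_json() + "\n")
    return paths
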