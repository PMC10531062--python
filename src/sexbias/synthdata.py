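"""Synthetic inputs with planted ground truth.

Every file dialect the pipeline consumes can be generated here with the
statistical structure the analysis assumes, so all stages are testable
without external downloads.

Expression model
----------------
The pipeline consumes already-normalized profiles, so expression is
simulated directly on a log scale: per-miRNA baseline ``mu_i ~ N(mu0,
tau)``, per-sample noise ``N(0, noise_sd)``.  A planted sex-biased miRNA
has the favored sex's samples shifted additively by ``effect_size *
noise_sd``, which makes rank-sum power analytically predictable.  The
truth table records the planted direction (``FB``/``MB``/``unbiased``)
per miRNA.

All generators are deterministic under their seed: identical seed and
configuration yield bit-identical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from sexbias import formats
from sexbias.formats import (
    AssociationTable,
    CategorySetCollection,
    ExpressionDataset,
    MiRNAAnnotation,
)

__all__ = [
    "SynthConfig",
    "generate_expression_dataset",
    "generate_annotation",
    "generate_family_file",
    "generate_association_table",
    "generate_category_sets",
    "generate_tsi_table",
    "generate_world",
    "SPECIES_BY_RANK",
]

#: Species prefixes available per clade rank (1 = human ... 5 = distal).
SPECIES_BY_RANK: dict[int, tuple[str, ...]] = {
    1: ("hsa",),
    2: ("ptr", "ggo", "ppy", "mml", "ppa", "sla"),
    3: ("mmu", "rno", "bta", "cfa", "ssc", "ocu", "eca", "oar", "mdo"),
    4: ("gga", "dre", "xtr", "aca", "tgu", "ola"),
    5: ("cel", "dme", "cin", "sma", "bfl", "spu"),
}


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic expression dataset.

    Defaults reflect the scale of a typical miRNA microarray study: on
    the order of a thousand profiled miRNAs, a few tens of samples per
    sex, a modest fraction of truly sex-biased miRNAs with the female
    direction dominating (the disease catalogs skew roughly 3:1 female),
    and a location shift of 1.5 within-group standard deviations.
    """

    n_mirnas: int = 1000
    n_female: int = 30
    n_male: int = 30
    frac_biased: float = 0.1
    frac_female_biased_of_biased: float = 0.75
    effect_size: float = 1.5
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    n_chromosomes: int = 22
    sex_chrom_share: float = 0.07
    cluster_planting: bool = False
    cluster_span_bp: int = 10_000
    seed: int = 0
    dataset_id: str = "SYN001"
    disease: str = "synthetic disease"
    disease_group: str = "Neoplasms"
    tissue_class: str = "neoplasms"

    def __post_init__(self) -> None:
        for name in ("n_mirnas", "n_female", "n_male", "n_chromosomes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("frac_biased", "frac_female_biased_of_biased", "sex_chrom_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be positive, got {self.noise_sd}")
        if self.cluster_span_bp < 1:
            raise ValueError("cluster_span_bp must be >= 1")


def _mirna_names(n: int) -> list[str]:
    return [f"hsa-mir-s{i + 1:04d}" for i in range(n)]


def generate_expression_dataset(
    config: SynthConfig,
) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Simulate one normalized expression dataset plus its truth table.

    Exactly ``round(n_mirnas * frac_biased)`` miRNAs carry a planted
    shift, of which ``round(. * frac_female_biased_of_biased)`` favor
    females.  Returns the dataset and a truth DataFrame with columns
    ``mirna`` and ``planted`` in {FB, MB, unbiased}.
    """
    rng = np.random.default_rng(config.seed)
    names = _mirna_names(config.n_mirnas)
    n_samples = config.n_female + config.n_male
    samples = [f"F{i + 1:04d}" for i in range(config.n_female)] + [
        f"M{i + 1:04d}" for i in range(config.n_male)
    ]

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_mirnas)
    values = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(config.n_mirnas, n_samples))

    n_biased = round(config.n_mirnas * config.frac_biased)
    n_fb = round(n_biased * config.frac_female_biased_of_biased)
    biased_idx = rng.choice(config.n_mirnas, size=n_biased, replace=False)
    fb_idx = biased_idx[:n_fb]
    mb_idx = biased_idx[n_fb:]

    shift = config.effect_size * config.noise_sd
    values[np.ix_(fb_idx, np.arange(config.n_female))] += shift
    values[np.ix_(mb_idx, np.arange(config.n_female, n_samples))] += shift

    planted = np.full(config.n_mirnas, "unbiased", dtype=object)
    planted[fb_idx] = "FB"
    planted[mb_idx] = "MB"
    truth = pd.DataFrame({"mirna": names, "planted": planted})

    matrix = pd.DataFrame(values, index=names, columns=samples)
    sample_sex = {s: ("F" if s.startswith("F") else "M") for s in samples}
    dataset = ExpressionDataset(
        dataset_id=config.dataset_id,
        matrix=matrix,
        sample_sex=sample_sex,
        disease=config.disease,
        disease_group=config.disease_group,
        tissue_class=config.tissue_class,
    )
    return dataset, truth


_CHROM_LENGTH = 100_000_000
_DEFAULT_GROUP_PROBS = (0.30, 0.20, 0.25, 0.15, 0.10)


def generate_annotation(
    mirnas,
    n_chromosomes: int = 22,
    seed: int = 0,
    sex_chrom_share: float = 0.07,
    group_probs=None,
    cluster_members=None,
    cluster_span_bp: int = 10_000,
    family_prob: float = 0.7,
) -> MiRNAAnnotation:
    """Random genomic annotation for the given miRNAs (or a count).

    Each precursor lands on ``chrX``/``chrY`` with probability
    ``sex_chrom_share`` (4:1 in favor of X), else on a uniform autosome;
    coordinates are 1-based inclusive with start < end.  ``group_probs``
    sets conservation-group sampling weights (G1..G5), either one vector
    for all miRNAs or a mapping miRNA -> vector for planted structure.
    ``cluster_members`` are placed in same-chromosome clusters of >= 3
    within ``cluster_span_bp``.  Families (``MIPF...`` accessions) are
    assigned to a random subset so that co-familial structure exists.
    """
    if isinstance(mirnas, int):
        mirnas = _mirna_names(mirnas)
    mirnas = list(mirnas)
    if len(mirnas) < 1 or n_chromosomes < 1:
        raise ValueError("need >= 1 miRNA and >= 1 chromosome")
    rng = np.random.default_rng(seed)
    autosomes = [f"chr{i + 1}" for i in range(n_chromosomes)]

    chroms, starts = [], []
    for _ in mirnas:
        if rng.random() < sex_chrom_share:
            chroms.append("chrX" if rng.random() < 0.8 else "chrY")
        else:
            chroms.append(autosomes[rng.integers(len(autosomes))])
        starts.append(int(rng.integers(1, _CHROM_LENGTH)))
    table = pd.DataFrame(
        {
            "chromosome": chroms,
            "start": starts,
        },
        index=pd.Index(mirnas, name="precursor_name"),
    )

    if cluster_members:
        # only autosomal members are re-placed, so the sex-chromosome
        # share stays at its configured value
        cluster_members = [
            m
            for m in cluster_members
            if m in table.index and table.at[m, "chromosome"] in set(autosomes)
        ]
        # chunks of 3-5 members anchored on a shared autosome window
        i = 0
        while i < len(cluster_members):
            size = int(rng.integers(3, 6))
            chunk = cluster_members[i : i + size]
            i += size
            if len(chunk) < 2:
                break
            anchor_chrom = autosomes[rng.integers(len(autosomes))]
            anchor = int(rng.integers(1, _CHROM_LENGTH - cluster_span_bp))
            offsets = rng.choice(cluster_span_bp, size=len(chunk), replace=False)
            for m, off in zip(chunk, offsets):
                table.at[m, "chromosome"] = anchor_chrom
                table.at[m, "start"] = anchor + int(off)

    lengths = rng.integers(60, 121, size=len(mirnas))
    table["end"] = table["start"] + lengths - 1
    table["strand"] = np.where(rng.random(len(mirnas)) < 0.5, "+", "-")

    if group_probs is None:
        group_probs = _DEFAULT_GROUP_PROBS
    labels = np.array(formats.CONSERVATION_GROUPS)
    if isinstance(group_probs, dict):
        groups = [
            labels[rng.choice(5, p=np.asarray(group_probs.get(m, _DEFAULT_GROUP_PROBS)))]
            for m in mirnas
        ]
    else:
        probs = np.asarray(group_probs, dtype=float)
        groups = labels[rng.choice(5, size=len(mirnas), p=probs / probs.sum())]
    table["conservation_group"] = groups

    families = []
    fam_counter = 0
    for _ in mirnas:
        if rng.random() < family_prob:
            fam_counter += 1
            families.append(f"MIPF{fam_counter:07d}")
        else:
            families.append("")
    table["family_accession"] = families
    return MiRNAAnnotation(table=table[
        ["chromosome", "start", "end", "strand", "conservation_group", "family_accession"]
    ])


#: Distinct-species count ranges per conservation group, used when a
#: family's species count is derived from its members' conservation.
_SPECIES_COUNT_BY_GROUP = {"G1": (1, 1), "G2": (2, 4), "G3": (4, 8), "G4": (8, 15), "G5": (12, 24)}


def species_counts_from_conservation(annotation: MiRNAAnnotation, seed: int = 0) -> dict[str, int]:
    """Draw a distinct-species count per family accession, consistent with
    each family's conservation group (more conserved -> more species)."""
    rng = np.random.default_rng(seed)
    counts: dict[str, int] = {}
    fam_col = annotation.table["family_accession"]
    for accession, sub in annotation.table[fam_col != ""].groupby("family_accession"):
        group = sub["conservation_group"].mode().iat[0]
        lo, hi = _SPECIES_COUNT_BY_GROUP.get(group, (1, 1))
        counts[str(accession)] = int(rng.integers(lo, hi + 1))
    return counts


def generate_family_file(
    annotation: MiRNAAnnotation,
    species_counts_per_family: dict[str, int],
    seed: int = 0,
) -> dict[str, list[str]]:
    """Family accession -> member list, re-writable via the miFam writer.

    Every family referenced by the annotation must have a requested
    distinct-species count; the human members come from the annotation
    and foreign members are drawn so the number of distinct species
    prefixes equals the requested count, using clades no deeper than the
    family's conservation group (so conservation re-derived from the
    family file agrees with the annotation).
    """
    rng = np.random.default_rng(seed)
    fam_col = annotation.table["family_accession"]
    referenced = sorted(set(fam_col[fam_col != ""]))
    missing = [a for a in referenced if a not in species_counts_per_family]
    if missing:
        raise ValueError(f"unknown family accessions (no species count): {missing}")

    group_rank = {g: i + 1 for i, g in enumerate(formats.CONSERVATION_GROUPS)}
    families: dict[str, list[str]] = {}
    for accession in referenced:
        sub = annotation.table[fam_col == accession]
        human_members = list(sub.index)
        group = sub["conservation_group"].mode().iat[0]
        deepest = group_rank.get(group, 1)
        want = int(species_counts_per_family[accession])
        stem = human_members[0].removeprefix("hsa-")
        members = list(human_members)
        prefixes: list[str] = []
        if want > 1 and deepest > 1:
            # one species of the deepest clade pins the conservation group
            pool_deep = list(SPECIES_BY_RANK[deepest])
            prefixes.append(pool_deep[rng.integers(len(pool_deep))])
            shallow = [p for r in range(2, deepest + 1) for p in SPECIES_BY_RANK[r] if p not in prefixes]
            extra = min(want - 2, len(shallow))
            if extra > 0:
                prefixes.extend(rng.choice(shallow, size=extra, replace=False).tolist())
        members.extend(f"{p}-{stem}" for p in prefixes)
        families[accession] = members
    return families


def generate_association_table(
    mirnas,
    n_diseases: int = 30,
    density: float = 0.1,
    seed: int = 0,
    density_map: dict[str, float] | None = None,
) -> AssociationTable:
    """Bernoulli miRNA-disease links over ``n_diseases`` disease terms.

    ``density`` is the expected fraction of (miRNA, disease) pairs
    present; ``density_map`` overrides it per miRNA (for planting wider
    disease spectra in chosen sets).  The disease universe always
    contains all ``n_diseases`` terms, even at density 0.
    """
    if not 0.0 <= density <= 1.0:
        raise ValueError(f"density must lie in [0, 1], got {density}")
    if isinstance(mirnas, int):
        mirnas = _mirna_names(mirnas)
    rng = np.random.default_rng(seed)
    diseases = [f"disease_{i + 1:02d}" for i in range(n_diseases)]
    pairs = set()
    for m in mirnas:
        d_m = density_map.get(m, density) if density_map else density
        if not 0.0 <= d_m <= 1.0:
            raise ValueError(f"density for {m} outside [0, 1]: {d_m}")
        keep = rng.random(n_diseases) < d_m
        pairs.update((m, d) for d, k in zip(diseases, keep) if k)
    return AssociationTable(pairs=pairs, disease_universe=set(diseases))


def generate_category_sets(
    mirnas,
    n_categories: int = 3,
    seed: int = 0,
    class_name: str = "function",
    size_range: tuple[int, int] = (5, 30),
    planted: dict[str, set[str]] | None = None,
) -> CategorySetCollection:
    """Random named miRNA subsets for over-representation testing.

    ``planted`` adds categories with exactly the given membership (e.g. a
    category that contains a known query, so enrichment must rank it
    first).
    """
    if isinstance(mirnas, int):
        mirnas = _mirna_names(mirnas)
    mirnas = list(mirnas)
    rng = np.random.default_rng(seed)
    lo = min(size_range[0], len(mirnas))
    hi = min(size_range[1], len(mirnas))
    sets: dict[str, set[str]] = {}
    for i in range(n_categories):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(mirnas, size=size, replace=False)
        sets[f"{class_name}_cat_{i + 1:02d}"] = set(members.tolist())
    for name, members in (planted or {}).items():
        sets[name] = set(members)
    return CategorySetCollection(class_name=class_name, sets=sets)


def generate_tsi_table(
    mirnas,
    seed: int = 0,
    base_shape: tuple[float, float] = (2.0, 4.0),
    boost: dict[str, float] | None = None,
) -> dict[str, float]:
    """Per-miRNA tissue-specificity scores in [0, 1].

    Background scores follow Beta(2, 4) (most miRNAs broadly expressed);
    ``boost`` adds a per-miRNA location shift (clipped into [0, 1]) to
    plant elevated specificity in chosen sets.
    """
    if isinstance(mirnas, int):
        mirnas = _mirna_names(mirnas)
    rng = np.random.default_rng(seed)
    scores = rng.beta(*base_shape, size=len(mirnas))
    out = {}
    for m, s in zip(mirnas, scores):
        if boost and m in boost:
            s = s + boost[m]
        out[m] = float(min(max(s, 0.0), 1.0))
    return out


# ---------------------------------------------------------------------------
# a fully consistent multi-dataset world


@dataclass
class SyntheticWorld:
    """Everything one end-to-end run needs, mutually consistent."""

    datasets: list[ExpressionDataset]
    truths: dict[str, pd.DataFrame]
    group_map: dict[str, str]
    tissue_map: dict[str, str]
    annotation: MiRNAAnnotation
    families: dict[str, list[str]]
    associations: AssociationTable
    tsi: dict[str, float]
    category_sets: dict[str, CategorySetCollection]
    mature_map: dict[str, list[str]] = field(default_factory=dict)


#: Conservation-group sampling weights planted per truth label: female-
#: biased miRNAs skew toward the deeply conserved groups, male-biased
#: less so, the background toward young groups.
_PLANT_GROUP_PROBS = {
    "FB": (0.05, 0.05, 0.10, 0.20, 0.60),
    "MB": (0.05, 0.10, 0.20, 0.25, 0.40),
    "unbiased": _DEFAULT_GROUP_PROBS,
}
_PLANT_TSI_BOOST = {"FB": 0.30, "MB": 0.15}
_PLANT_ASSOC_DENSITY = {"FB": 0.35, "MB": 0.20, "unbiased": 0.08}


def generate_world(
    base_config: SynthConfig | None = None,
    groups: tuple[str, ...] = ("Infectious", "Neoplasms"),
    seed: int = 0,
) -> SyntheticWorld:
    """Generate a multi-dataset scenario with the qualitative pattern the
    analysis is designed to detect.

    One dataset per disease group shares a common miRNA universe.  The
    planted sex-biased miRNAs are more conserved than the background
    (female-biased most), carry higher tissue-specificity and wider
    disease spectra, sit in genomic clusters, and ~7% of all miRNAs lie
    on sex chromosomes.  Category sets include one planted category per
    class built around the female-biased set.
    """
    base = base_config or SynthConfig()
    ss = np.random.SeedSequence(seed)
    sub = ss.spawn(8)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in sub]

    tissue_for_group = {
        "Infectious": "peripheral_blood",
        "Neoplasms": "neoplasms",
        "Endocrine diseases": "other",
        "Developmental anomalies": "other",
    }

    datasets: list[ExpressionDataset] = []
    truths: dict[str, pd.DataFrame] = {}
    group_map: dict[str, str] = {}
    tissue_map: dict[str, str] = {}
    for i, group in enumerate(groups):
        cfg = replace(
            base,
            seed=seeds[0] + i,
            dataset_id=f"SYN{i + 1:03d}",
            disease=f"synthetic {group.lower()} disease",
            disease_group=group,
            tissue_class=tissue_for_group.get(group, "other"),
        )
        ds, truth = generate_expression_dataset(cfg)
        datasets.append(ds)
        truths[ds.dataset_id] = truth
        group_map[ds.dataset_id] = group
        tissue_map[ds.dataset_id] = cfg.tissue_class

    mirnas = list(datasets[0].matrix.index)
    # union truth label per miRNA (FB beats MB beats unbiased on conflict,
    # only used to plant correlated attributes)
    label = {m: "unbiased" for m in mirnas}
    for truth in truths.values():
        for m, lab in zip(truth["mirna"], truth["planted"]):
            if lab == "FB" or (lab == "MB" and label[m] == "unbiased"):
                label[m] = lab

    biased = [m for m in mirnas if label[m] != "unbiased"]
    annotation = generate_annotation(
        mirnas,
        n_chromosomes=base.n_chromosomes,
        seed=seeds[1],
        sex_chrom_share=base.sex_chrom_share,
        group_probs={m: _PLANT_GROUP_PROBS[label[m]] for m in mirnas},
        cluster_members=biased,
        cluster_span_bp=base.cluster_span_bp,
    )
    species_counts = species_counts_from_conservation(annotation, seed=seeds[2])
    families = generate_family_file(annotation, species_counts, seed=seeds[2])

    associations = generate_association_table(
        mirnas,
        n_diseases=30,
        density=_PLANT_ASSOC_DENSITY["unbiased"],
        seed=seeds[3],
        density_map={m: _PLANT_ASSOC_DENSITY[label[m]] for m in mirnas},
    )
    tsi = generate_tsi_table(
        mirnas,
        seed=seeds[4],
        boost={m: _PLANT_TSI_BOOST[label[m]] for m in mirnas if label[m] in _PLANT_TSI_BOOST},
    )

    rng = np.random.default_rng(seeds[5])
    fb_all = [m for m in mirnas if label[m] == "FB"]
    category_sets = {}
    for class_idx, class_name in enumerate(("function", "disease", "TF")):
        planted_members = set(
            rng.choice(fb_all, size=max(3, len(fb_all) // 2), replace=False).tolist()
        ) if fb_all else set()
        planted = {f"{class_name}_planted_fb": planted_members} if planted_members else None
        category_sets[class_name] = generate_category_sets(
            mirnas,
            n_categories=8,
            seed=seeds[6] + class_idx,
            class_name=class_name,
            planted=planted,
        )

    mature_map = {m: [f"{m.replace('mir', 'miR', 1)}-5p", f"{m.replace('mir', 'miR', 1)}-3p"] for m in mirnas[:50]}
    return SyntheticWorld(
        datasets=datasets,
        truths=truths,
        group_map=group_map,
        tissue_map=tissue_map,
        annotation=annotation,
        families=families,
        associations=associations,
        tsi=tsi,
        category_sets=category_sets,
        mature_map=mature_map,
    )
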