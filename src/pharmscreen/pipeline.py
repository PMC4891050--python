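"""End-to-end orchestration of the screening funnel and the triage stage.

``run_screen`` executes the whole cascade —

    pocket -> interaction map -> clustering -> hypotheses -> property filter
    -> feature matching + fit ranking -> top-fit cut -> rigid minimization +
    energy rescoring -> top-energy cut -> diversity selection -> final set

— logging one line per stage, and emits the ranked-hit table, the funnel
report, and a per-residue energy table plus H-bond report for the top hit.
``run_triage`` applies the strict RU / inhibition-ratio thresholds to a
readout table.  All randomness flows from the single config seed; reruns with
the same config are byte-identical.

Configs are flat ``key=value`` text (diff-able, language-neutral); defaults
are dataclass fields and can be dumped with :func:`dump_config`.

A note on hypothesis choice for synthetic runs: a planted library guarantees
that kind-deficient decoys can never complete a match *against the planted
hypothesis*.  Screening such a library against every enumerated hypothesis
would let a decoy legitimately max-fit some subset that happens not to ask
for the omitted kind, which says nothing about the planted truth.  Synthetic
end-to-end runs therefore screen against the planted hypothesis
(``hypothesis_source=planted``); ``hypothesis_source=enumerate`` screens real
libraries against the full enumeration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, asdict

import numpy as np

from . import imap as im
from .structure import PocketSphere, ProteinStructure, parse_pdb, sphere_from_residues
from .ligands import compute_properties, parse_sdf, path_fingerprint
from .screen import (FunnelReport, MatchResult, diversity_select, property_filter,
                     screen_library, select_top)
from .energy import (EnergyParams, detect_hbonds, hbond_table, ligand_atom_set,
                     minimize_pose, per_residue_decomposition, per_residue_table,
                     protein_atom_set)
from .triage import read_screen_records, triage_hits, triage_report
from . import synth

logger = logging.getLogger("pharmscreen.pipeline")

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "parse_config",
    "dump_config",
    "planted_hypothesis",
    "run_screen",
    "run_triage",
]


@dataclass
class PipelineConfig:
    # randomness
    seed: int = 1
    # pocket
    pocket_source: str = "synthetic"      # "synthetic" or a PDB path
    pocket_center: str = ""               # "x,y,z"; blank -> synthetic default / residues
    pocket_radius: float = 0.0            # 0 -> synthetic default / from residues
    sphere_residues: str = ""             # e.g. "A:64,A:73"
    sphere_padding: float = 3.0
    # interaction map
    cluster_cutoff: float = im.CLUSTER_CUTOFF
    kmin: int = 3
    kmax: int = 7
    min_pair_dist: float = im.MIN_PAIR_DIST
    exclusion_margin: float = 2.0
    # hypotheses
    hypothesis_source: str = "planted"    # "planted" | "enumerate"
    central_rmax: float = 4.5             # planted-hypothesis feature radius bound
    max_hypotheses: int = 50
    # library
    library_source: str = "planted"      # "planted" or an SDF path
    n_active: int = 5
    n_decoy: int = 45
    displacement: float = 0.5
    # property filter
    mw_max: float = 500.0
    logp_max: float = 5.0
    logs_min: float = -6.0
    # funnel sizes (the original campaign used 5000 -> 1000 -> 100)
    top_fit: int = 20
    top_energy: int = 10
    n_final: int = 5
    sim_threshold: float = 0.9
    # energy
    shell: float = 10.0
    pair_cutoff: float = 10.0
    # triage
    ru_min: float = 20.0
    inh_min: float = 30.0
    records: str = ""                     # CSV path; blank -> synthetic table
    log_level: str = "INFO"

    def __post_init__(self):
        sizes = [self.top_fit, self.top_energy, self.n_final]
        if any(s <= 0 for s in sizes):
            raise ValueError("funnel sizes must be positive")
        if not (self.top_fit >= self.top_energy >= self.n_final):
            raise ValueError("funnel sizes must be non-increasing")


def parse_config(text: str) -> PipelineConfig:
    """Parse flat key=value text; unknown keys are rejected."""
    kwargs: dict = {}
    types = {f.name: f.type for f in fields(PipelineConfig)}
    defaults = PipelineConfig()
    for i, line in enumerate(text.splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"config line {i + 1} is not key=value: {line!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in types:
            raise ValueError(f"unknown config key {key!r} on line {i + 1}")
        current = getattr(defaults, key)
        kwargs[key] = type(current)(value) if not isinstance(current, str) else value
    return PipelineConfig(**kwargs)


def dump_config(config: PipelineConfig | None = None) -> str:
    config = config or PipelineConfig()
    return "".join(f"{k}={v}\n" for k, v in asdict(config).items())


@dataclass
class PipelineResult:
    report: FunnelReport
    final: list[MatchResult]
    energies: dict[str, float]
    artifacts: dict[str, str] = field(default_factory=dict)  # name -> text
    labels: dict[str, str] = field(default_factory=dict)     # planted truth


def planted_hypothesis(features: list[im.PharmacophoreFeature], pocket: PocketSphere,
                       rmax: float, min_pair_dist: float) -> im.Hypothesis:
    """First enumerated 3-feature hypothesis covering all three kinds, using
    only features within `rmax` of the pocket center (the open cleft
    interior, where a planted ligand cannot collide with the pocket wall)."""
    central = [f for f in features
               if float(np.linalg.norm(f.position - pocket.center)) <= rmax]
    for hyp in im.enumerate_hypotheses(central, 3, 3, min_pair_dist):
        if set(hyp.kinds) == {im.DONOR, im.ACCEPTOR, im.HYDROPHOBIC}:
            return hyp
    raise RuntimeError("no all-kind hypothesis found in the pocket interior")


def _load_pocket(config: PipelineConfig) -> tuple[ProteinStructure, PocketSphere]:
    if config.pocket_source == "synthetic":
        toy = synth.make_toy_pocket(seed=config.seed)
        structure = parse_pdb(toy.pdb_text, structure_id=f"toy-seed{config.seed}")
        sphere = synth.toy_pocket_sphere()
        if config.pocket_radius > 0:
            sphere = PocketSphere(sphere.center, config.pocket_radius)
        return structure, sphere
    with open(config.pocket_source) as fh:
        structure = parse_pdb(fh.read(), structure_id=config.pocket_source)
    if config.sphere_residues:
        keys = []
        for tok in config.sphere_residues.split(","):
            chain, _, num = tok.strip().partition(":")
            keys.append((chain, int(num)))
        return structure, sphere_from_residues(structure, keys, config.sphere_padding)
    if not config.pocket_center or config.pocket_radius <= 0:
        raise ValueError("file pockets need sphere_residues or pocket_center+pocket_radius")
    center = np.array([float(x) for x in config.pocket_center.split(",")], float)
    return structure, PocketSphere(center, config.pocket_radius)


def run_screen(config: PipelineConfig) -> PipelineResult:
    """Execute the full funnel; see the module docstring for the stage order."""
    logging.basicConfig(level=config.log_level)
    report = FunnelReport()

    structure, sphere = _load_pocket(config)
    logger.info("stage pocket: %d residues, sphere r=%.1f A", len(structure.residues),
                sphere.radius)

    imap_obj = im.build_interaction_map(
        structure, sphere, cluster_cutoff=config.cluster_cutoff,
        margin=config.exclusion_margin)
    logger.info("stage map: %d features, %d exclusion spheres",
                len(imap_obj.features), len(imap_obj.exclusions))

    planted = planted_hypothesis(imap_obj.features, sphere, config.central_rmax,
                                 config.min_pair_dist)
    if config.hypothesis_source == "planted":
        hypotheses = [planted]
    else:
        hypotheses = im.enumerate_hypotheses(
            imap_obj.features, config.kmin, config.kmax,
            config.min_pair_dist)[:config.max_hypotheses]
    logger.info("stage hypotheses: %d queries", len(hypotheses))

    if config.library_source == "planted":
        sdf_text, labels = synth.make_planted_library(
            planted, config.n_active, config.n_decoy,
            displacement=config.displacement, seed=config.seed)
        library = parse_sdf(sdf_text)
    else:
        with open(config.library_source) as fh:
            library = parse_sdf(fh.read())
        labels = {}
    for lig in library:
        compute_properties(lig)
    report.record("library", [l.id for l in library])
    logger.info("stage library: %d ligands", len(library))

    filtered = property_filter(library, config.mw_max, config.logp_max, config.logs_min)
    report.record("property_filter", [l.id for l in filtered])
    logger.info("stage property_filter: %d kept", len(filtered))

    ranked = screen_library(filtered, hypotheses, imap_obj.exclusions, report)
    logger.info("stage matched: %d ligands with a valid pose", len(ranked))

    top_fit = select_top(ranked, config.top_fit)
    report.record("top_fit", [r.ligand_id for r in top_fit])
    logger.info("stage top_fit: %d", len(top_fit))

    # rigid minimization + energy rescoring
    ligands_by_id = {l.id: l for l in library}
    params = EnergyParams(pair_cutoff=config.pair_cutoff)
    energies: dict[str, float] = {}
    minimized_pose: dict[str, np.ndarray] = {}
    for r in top_fit:
        lig_set = ligand_atom_set(ligands_by_id[r.ligand_id], r.pose)
        prot_set = protein_atom_set(structure)
        min_set, trace = minimize_pose(lig_set, prot_set, params, seed=config.seed)
        energies[r.ligand_id] = trace[-1]
        heavy_idx = [a.GetIdx() for a in ligands_by_id[r.ligand_id].mol.GetAtoms()
                     if a.GetSymbol() not in ("H", "D")]
        pose = r.pose.copy()
        pose[heavy_idx] = min_set.coords
        minimized_pose[r.ligand_id] = pose
    by_energy = sorted(top_fit, key=lambda r: (energies[r.ligand_id], r.ligand_id))
    top_energy = select_top(by_energy, config.top_energy)
    report.record("top_energy", [r.ligand_id for r in top_energy])
    logger.info("stage top_energy: %d", len(top_energy))

    fingerprints = {l.id: path_fingerprint(l) for l in library}
    final = diversity_select(top_energy, fingerprints, config.n_final,
                             config.sim_threshold)
    if len(final) < min(config.n_final, len(top_energy)):
        logger.warning("diversity selection returned %d < requested %d",
                       len(final), config.n_final)
    report.record("final", [r.ligand_id for r in final])
    logger.info("stage final: %d compounds", len(final))

    artifacts = {"funnel.tsv": report.to_tsv(), "map.json": im.map_to_json(imap_obj)}
    rows = ["ligand_id\thypothesis_id\tconformer\tfit\tenergy_kcal_mol"]
    for r in top_energy:
        rows.append(f"{r.ligand_id}\t{r.hypothesis_id}\t{r.conformer_index}"
                    f"\t{r.fit:.4f}\t{energies[r.ligand_id]:.4f}")
    artifacts["hits.tsv"] = "\n".join(rows) + "\n"

    if final:
        top = final[0]
        top_lig = ligands_by_id[top.ligand_id]
        lig_set = ligand_atom_set(top_lig, minimized_pose[top.ligand_id])
        score = per_residue_decomposition(lig_set, structure, params, shell=config.shell)
        artifacts["per_residue.tsv"] = per_residue_table(score)
        bonds = detect_hbonds(top_lig, minimized_pose[top.ligand_id], structure)
        artifacts["hbonds.tsv"] = hbond_table(bonds)

    return PipelineResult(report=report, final=final, energies=energies,
                          artifacts=artifacts, labels=labels)


def run_triage(config: PipelineConfig) -> tuple[list[str], list[str], list[str], str]:
    """Apply strict RU / inhibition thresholds to a readout table.

    Returns (ru_hits, inhibition_hits, intersection, TSV report).
    """
    if config.records:
        with open(config.records) as fh:
            records = read_screen_records(fh.read())
    else:
        df = synth.make_screen_table(ru_min=config.ru_min, inh_min=config.inh_min,
                                     seed=config.seed)
        records = read_screen_records(df.to_csv(index=False))
    ru_hits, inh_hits, inter = triage_hits(records, config.ru_min, config.inh_min)
    logger.info("triage: %d RU hits, %d inhibition hits, %d in both",
                len(ru_hits), len(inh_hits), len(inter))
    return ru_hits, inh_hits, inter, triage_report(records, config.ru_min, config.inh_min)
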