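"""Backend contract, deterministic mock predictor, and the four run modes.

The predictor is pluggable behind :class:`PredictorBackend`: ``invoke`` takes
a validated feature container and returns models of the query length with
per-residue confidence, and never mutates its input.  A real AlphaFold2-style
backend is an external-process adapter (feature hand-off, model collection);
the :class:`MockBackend` shipped here is deterministic and makes every run
mode testable at desk scale: positions covered by the highest-weight template
copy that template's coordinates plus seeded Gaussian noise (sigma 0.2 A,
confidence 90), uncovered positions are built as an extended chain
(confidence 50).

Run modes:

* ``guided``  — build the container from the configured channels, predict,
  analyze;
* ``naive``   — cluster the supplied/harvested templates into structural
  states (default two) and run one guided branch per cluster with a joint
  state analysis;
* ``mutation``— apply variants, predict, revert the variants with the
  prediction as template, predict again;
* ``mosaic``  — split a large target into overlapping segments, run each,
  merge on the shared anchors.

Every run writes its resolved configuration next to the outputs and is
bit-reproducible from that configuration plus the seed with the mock backend.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Protocol

import numpy as np
import yaml

from . import msa_ops, template_ops, variants as variants_mod
from .assembly import AssemblyPlan, ChainSpec, concatenate, disengage
from .feature_store import FeatureSet, validate
from .fixtures import PHI_PSI, build_backbone, _assemble
from .model_analysis import RankReport, rank_models, write_report
from .mosaic import merge as mosaic_merge, seed_next, split
from .structclust import StateAnalysis, analyze_ensemble
from .structures import CA, StructureModel

log = logging.getLogger("foldguide")


class PredictorBackend(Protocol):
    """Contract every prediction backend satisfies."""

    max_length: int
    supports_templates: bool

    def invoke(self, fs: FeatureSet, n_models: int, seed: int
               ) -> list[StructureModel]:
        ...


MOCK_NOISE_SIGMA = 0.2
MOCK_COVERED_PLDDT = 90.0
MOCK_UNCOVERED_PLDDT = 50.0


class MockBackend:
    """Deterministic stand-in predictor for desk-scale runs and tests."""

    max_length = 10000
    supports_templates = True

    def __init__(self, noise_sigma: float = MOCK_NOISE_SIGMA):
        self.noise_sigma = noise_sigma

    def invoke(self, fs: FeatureSet, n_models: int, seed: int
               ) -> list[StructureModel]:
        problems = validate(fs)
        if problems:
            raise ValueError("invalid FeatureSet: " + "; ".join(problems))
        return [self._one_model(fs, seed + i, i) for i in range(n_models)]

    def _one_model(self, fs: FeatureSet, seed: int, rank: int
                   ) -> StructureModel:
        L = len(fs)
        rng = np.random.default_rng(seed)
        # baseline: extended chain for the full length
        backbone = build_backbone([PHI_PSI["extended"]] * L)
        base = _assemble(fs.query.sequence, backbone, name=f"mock_{rank}")
        confidence = np.full(L, MOCK_UNCOVERED_PLDDT)
        if fs.templates:
            best = max(fs.templates, key=lambda t: (t.sum_prob, t.name))
            covered = best.covered & (best.atom_mask[:, CA] > 0)
            base.atom_positions[covered] = best.atom_positions[covered]
            base.atom_mask[covered] = best.atom_mask[covered]
            if self.noise_sigma > 0:
                noise = rng.normal(scale=self.noise_sigma,
                                   size=(int(covered.sum()), 37, 3))
                base.atom_positions[covered] += noise
            base.atom_positions[base.atom_mask == 0] = 0.0
            confidence[covered] = MOCK_COVERED_PLDDT
        base.confidence = confidence
        base.residue_numbers = np.arange(1, L + 1, dtype=np.int64)
        return base


def get_backend(name: str, **kwargs) -> PredictorBackend:
    if name == "mock":
        return MockBackend(**kwargs)
    log.warning("backend %r is not available in this installation; "
                "falling back to the deterministic mock backend", name)
    return MockBackend(**kwargs)


# --- Configuration ----------------------------------------------------------

class ConfigError(ValueError):
    pass


@dataclass
class TemplateConfig:
    path: str
    relabel: str = "keep"                 # keep|polyalanine|query|custom
    custom_sequence: Optional[str] = None
    exception_region: Optional[list] = None
    exception_mode: str = "query"
    region: Optional[list] = None
    mapping: Optional[list] = None        # explicit [[q, t], ...] 0-based
    truncate_cbeta: bool = False
    sum_prob: float = 1.0


@dataclass
class MSAConfig:
    path: str
    format: str = "a3m"
    region: Optional[list] = None
    mask: Optional[list] = None           # regions to mask after merging
    depth: Optional[int] = None
    depth_strategy: str = "top"


@dataclass
class MosaicConfig:
    max_len: int = 900
    overlap: int = 60
    seed_policy: str = "best_of_previous"


@dataclass
class RunConfig:
    """Schema-validated run description (YAML-friendly)."""

    mode: str
    chains: list[dict]
    output_dir: str = "foldguide_out"
    linker_mode: str = "index_gap"
    index_gap: int = 200
    physical_linker: str = "GGGGS"
    templates: list[dict] = field(default_factory=list)
    msa: list[dict] = field(default_factory=list)
    variants: list = field(default_factory=list)
    declared_interfaces: list = field(default_factory=list)
    mosaic: dict = field(default_factory=dict)
    naive_groups: int = 2
    backend: str = "mock"
    backend_options: dict = field(default_factory=dict)
    n_models: int = 1
    seed: int = 0

    _MODES = ("guided", "naive", "mutation", "mosaic")

    def __post_init__(self):
        if self.mode not in self._MODES:
            raise ConfigError(f"mode must be one of {self._MODES}, "
                              f"got {self.mode!r}")
        if not self.chains:
            raise ConfigError("at least one chain is required")
        for c in self.chains:
            if "sequence" not in c or "chain_id" not in c:
                raise ConfigError("each chain needs chain_id and sequence")
        if self.mode == "mutation" and not self.variants:
            raise ConfigError("mutation mode requires variants")
        if self.n_models < 1:
            raise ConfigError("n_models must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: not a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def assembly_plan(self) -> AssemblyPlan:
        return AssemblyPlan(
            chains=[ChainSpec(**c) for c in self.chains],
            linker_mode=self.linker_mode, index_gap=self.index_gap,
            physical_linker=self.physical_linker)


# --- Channel construction ---------------------------------------------------

def build_features(config: RunConfig) -> FeatureSet:
    """Assemble the FeatureSet from the configured guidance channels."""
    plan = config.assembly_plan()
    fs = concatenate(plan)

    blocks = []
    for raw in config.msa:
        mc = MSAConfig(**raw)
        block = msa_ops.parse_alignment(
            mc.path, mc.format,
            _region_query(fs, mc.region, plan))
        if mc.depth is not None:
            block = msa_ops.reduce_depth(block, mc.depth, mc.depth_strategy,
                                         seed=config.seed)
        region = (msa_ops.RegionSelection.parse(mc.region)
                  if mc.region else None)
        blocks.append((block, region, mc.mask))
    if blocks:
        merged = msa_ops.merge([(b, r) for b, r, _ in blocks], fs.query,
                               plan=plan)
        for _, _, mask in blocks:
            if mask:
                merged = msa_ops.mask_region(
                    merged, msa_ops.RegionSelection.parse(mask), plan=plan)
        fs = msa_ops.set_msa(fs, merged, source="config")

    for raw in config.templates:
        tc = TemplateConfig(**raw)
        structure = StructureModel.from_file(tc.path)
        mapping = "auto"
        if tc.mapping:
            mapping = template_ops.AlignmentMap(
                pairs=[tuple(p) for p in tc.mapping])
        region = (msa_ops.RegionSelection.parse(tc.region)
                  if tc.region else None)
        t = template_ops.structure_to_template(
            structure, fs.query, mapping=mapping, placement=region,
            plan=plan, sum_prob=tc.sum_prob)
        mode = template_ops.RelabelMode(
            mode=tc.relabel, sequence=tc.custom_sequence,
            exception=(msa_ops.RegionSelection.parse(tc.exception_region)
                       if tc.exception_region else None),
            exception_mode=tc.exception_mode)
        t = template_ops.relabel_template(t, mode, fs.query, plan=plan)
        if tc.truncate_cbeta:
            t = template_ops.truncate_to_cbeta(t)
        fs.templates.append(t)
        fs.record("add_template", path=tc.path, relabel=tc.relabel,
                  truncate_cbeta=tc.truncate_cbeta)

    if config.variants:
        fs = variants_mod.apply_variants(
            fs, variants_mod.VariantSpec.parse(config.variants))
    return fs


def _region_query(fs: FeatureSet, region, plan) -> str:
    if not region:
        return fs.query.sequence
    cols = msa_ops.RegionSelection.parse(region).resolve(len(fs), plan)
    return "".join(fs.query.sequence[c] for c in cols)


# --- Run modes --------------------------------------------------------------

@dataclass
class RunResult:
    models: list[StructureModel]
    report: RankReport
    state: Optional[StateAnalysis]
    outdir: Path
    features: Optional[FeatureSet] = None


def run(config: RunConfig) -> RunResult:
    """Execute a run mode and write all artifacts to the output directory."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "resolved_config.yaml")
    backend = get_backend(config.backend, **config.backend_options)
    runner = {"guided": _run_guided, "naive": _run_naive,
              "mutation": _run_mutation, "mosaic": _run_mosaic}[config.mode]
    result = runner(config, backend, outdir)
    for m in result.models:
        m.to_pdb(outdir / f"{m.name}.pdb")
    write_report(result.report, outdir, state=result.state)
    _write_log(result, outdir)
    return result


def _write_log(result: RunResult, outdir: Path) -> None:
    lines = []
    if result.features is not None:
        for entry in result.features.provenance:
            lines.append(json.dumps(entry, sort_keys=True))
    (outdir / "provenance.log").write_text("\n".join(lines) + "\n")


def _analyze(config: RunConfig, fs: FeatureSet,
             models: list[StructureModel]) -> RankReport:
    declared = [tuple(p) for p in config.declared_interfaces]
    return rank_models(models, fs=fs, declared_interfaces=declared)


def _predict_and_disengage(config: RunConfig, backend, fs: FeatureSet,
                           tag: str, seed: int) -> list[StructureModel]:
    plan = fs.assembly
    raw_models = backend.invoke(fs, config.n_models, seed)
    out = []
    for i, m in enumerate(raw_models):
        m.name = f"{tag}_{i}"
        if plan is not None and len(plan.chain_segments()) > 1:
            dm = disengage(m, plan)  # carries per-residue confidence through
            dm.name = m.name
            out.append(dm)
        else:
            out.append(m)
    return out


def _run_guided(config: RunConfig, backend, outdir: Path) -> RunResult:
    fs = build_features(config)
    from .feature_store import save as save_features
    save_features(fs, outdir / "features.npz")
    models = _predict_and_disengage(config, backend, fs, "guided",
                                    config.seed)
    report = _analyze(config, fs, models)
    state = None
    if len(models) >= 2:
        try:
            state = analyze_ensemble(models, seed=config.seed)
        except ValueError:
            state = None
    return RunResult(models=models, report=report, state=state,
                     outdir=outdir, features=fs)


def _run_naive(config: RunConfig, backend, outdir: Path) -> RunResult:
    """Cluster the template stack into states; one prediction branch each."""
    fs = build_features(config)
    if len(fs.templates) < 2:
        raise ConfigError("naive mode needs at least two templates to cluster")
    clustering = template_ops.cluster_templates(
        fs.templates, k=config.naive_groups, seed=config.seed)
    fs.record("cluster_templates", k=config.naive_groups,
              labels=clustering.labels.tolist())
    all_models: list[StructureModel] = []
    branch_members: list[list[str]] = []
    for g, group in enumerate(clustering.groups):
        branch = fs.copy()
        branch.templates = [t.copy() for t in group]
        branch.record("naive_branch", group=g,
                      templates=[t.name for t in group])
        models = _predict_and_disengage(config, backend, branch,
                                        f"state{g}", config.seed + g)
        branch_members.append([m.name for m in models])
        all_models.extend(models)
    report = _analyze(config, fs, all_models)
    state = None
    try:
        state = analyze_ensemble(all_models, seed=config.seed,
                                 k=len(clustering.groups))
    except ValueError:
        state = None
    result = RunResult(models=all_models, report=report, state=state,
                       outdir=outdir, features=fs)
    (outdir / "branches.json").write_text(
        json.dumps({"n_branches": len(clustering.groups),
                    "members": branch_members}, indent=1))
    return result


def _run_mutation(config: RunConfig, backend, outdir: Path) -> RunResult:
    """Two-step: predict the mutant, revert with the prediction as template."""
    plan = config.assembly_plan()
    original = concatenate(plan).query.sequence
    fs_mutant = build_features(config)
    mutant_models = backend.invoke(fs_mutant, 1, config.seed)
    mutant_models[0].name = "mutant_0"
    fs_revert = variants_mod.revert_cycle(fs_mutant, mutant_models[0],
                                          original)
    models = _predict_and_disengage(config, backend, fs_revert, "reverted",
                                    config.seed + 1)
    report = _analyze(config, fs_revert, models)
    return RunResult(models=models, report=report, state=None,
                     outdir=outdir, features=fs_revert)


def _run_mosaic(config: RunConfig, backend, outdir: Path) -> RunResult:
    """Split, predict per segment (optionally seeded), merge on anchors."""
    plan = config.assembly_plan()
    fs_full = build_features(config)
    mc = MosaicConfig(**config.mosaic) if config.mosaic else MosaicConfig()
    mplan = split(plan, mc.max_len, mc.overlap)
    mplan.seed_policy = mc.seed_policy
    segment_models: list[StructureModel] = []
    for idx, seg in enumerate(mplan.segments):
        sub_fs = _segment_features(fs_full, seg)
        for tmpl in seg.recipe.get("templates", []):
            sub_fs.templates.append(tmpl)
        sub_models = backend.invoke(sub_fs, 1, config.seed + idx)
        model = sub_models[0]
        model.name = f"segment_{idx}"
        segment_models.append(model)
        if mplan.seed_policy == "best_of_previous" and idx == 0:
            mplan = seed_next(mplan, model, best_segment=0)
    merged, merge_report = mosaic_merge(segment_models, mplan)
    merged.name = "mosaic_0"
    if len(plan.chain_segments()) > 1 and \
            len(merged) == plan.concatenated_length():
        merged = disengage(merged, plan)
        merged.name = "mosaic_0"
    report = _analyze(config, fs_full, [merged])
    (outdir / "mosaic.json").write_text(json.dumps({
        "segments": [[s.start, s.stop] for s in mplan.segments],
        "anchors": [list(a) for a in mplan.shared_anchors],
        "anchor_rmsds": merge_report.anchor_rmsds}, indent=1))
    return RunResult(models=[merged], report=report, state=None,
                     outdir=outdir, features=fs_full)


def _segment_features(fs: FeatureSet, seg) -> FeatureSet:
    """Restrict a FeatureSet to a mosaic segment's columns."""
    from .feature_store import MSABlock, QueryFeatures
    cols = np.arange(seg.start, seg.stop)
    q = fs.query
    query = QueryFeatures(
        sequence="".join(q.sequence[c] for c in cols),
        aatype=q.aatype[cols].copy(),
        residue_index=q.residue_index[cols].copy(),
        between_segment_flags=q.between_segment_flags[cols].copy(),
    )
    msa = MSABlock(rows=fs.msa.rows[:, cols].copy(),
                   deletion_counts=fs.msa.deletion_counts[:, cols].copy(),
                   row_labels=list(fs.msa.row_labels))
    msa.rows[0] = query.aatype
    msa.deletion_counts[0] = 0
    out = FeatureSet(query=query, msa=msa)
    for t in fs.templates:
        if not t.covered[cols].any():
            continue
        sub = t.copy()
        sub.labels = t.labels[cols].copy()
        sub.atom_positions = t.atom_positions[cols].copy()
        sub.atom_mask = t.atom_mask[cols].copy()
        out.templates.append(sub)
    out.record("segment_features", start=int(seg.start), stop=int(seg.stop))
    return out
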