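"""End-to-end wiring: simulate -> filter -> constructs -> controls ->
features -> directional summary.

This is the path the numbered analysis drivers, the acceptance script and
the recovery/calibration suites all run; it operates on in-memory objects
(no file round-trips) so repeated seeded runs are cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .annotation import EIEIEConstruct, extract_sequences
from .controls import (
    ControlConfig,
    build_event_construct,
    sample_external_controls,
    sample_internal_control,
    select_external_control_genes,
)
from .events import EventSet, events_from_frame, filter_events, split_by_direction
from .features import (
    compute_features,
    default_branch_point_model,
    features_to_frame,
    train_splice_site_model,
)
from .simulate import SimBundle, SimConfig, generate_bundle
from .stats import ComparisonSummary, build_summary

__all__ = ["PipelineResult", "run_feature_comparison", "filtered_event_sets"]


@dataclass
class PipelineResult:
    bundle: SimBundle
    filtered: dict[str, EventSet]
    more_skipped: EventSet
    less_skipped: EventSet
    event_constructs: dict[str, list[EIEIEConstruct]]   # per direction
    internal_constructs: dict[str, list[EIEIEConstruct]]
    external_constructs: list[EIEIEConstruct]
    feature_frames: dict[str, pd.DataFrame]
    summary: ComparisonSummary
    external_gene_ids: list[str] = field(default_factory=list)
    n_internal_unplaceable: int = 0

    def long_table_tsv(self) -> str:
        """Deterministic long-format comparison table (for diffing runs)."""
        return self.summary.to_long_frame().to_csv(sep="\t", index=False)


def filtered_event_sets(bundle: SimBundle, p_max: float = 0.05,
                        fdr_max: float = 0.05) -> dict[str, EventSet]:
    if bundle.event_tables is None:
        raise ValueError("bundle has no event tables")
    out = {}
    for cls_name, df in bundle.event_tables.items():
        es = events_from_frame(df, cls_name, provenance=f"sim-seed-{bundle.cfg.seed}")
        out[cls_name] = filter_events(es, p_max=p_max, fdr_max=fdr_max)
    return out


def run_feature_comparison(
    cfg: SimConfig,
    n_external: int = 100,
    alpha: float = 0.05,
    bundle: SimBundle | None = None,
) -> PipelineResult:
    """The full construct-and-compare analysis on one synthetic bundle.

    Event constructs come from the filtered SE rows, split by skipping
    direction (patient as rMATS sample 1). Internal controls are one
    non-overlapping window per event gene, drawn from the gene's reference
    transcript and grouped by the direction of that gene's events; external
    controls are one window per selected top-expressed gene. All constructs
    are sequence-extracted, scored with an annotation-trained splice-site
    model and the consensus branch-point model, and compared feature by
    feature.
    """
    if bundle is None:
        bundle = generate_bundle(cfg)
    annotation = bundle.annotation
    filtered = filtered_event_sets(bundle)
    more, less = split_by_direction(filtered["SE"], patient_is_sample1=True)

    # event constructs, grouped per gene for the overlap constraint
    per_gene: dict[str, list[EIEIEConstruct]] = {}
    event_constructs = {"more": [], "less": []}
    for direction, es in (("more", more), ("less", less)):
        for ev in es:
            c = build_event_construct(ev)
            event_constructs[direction].append(c)
            per_gene.setdefault(ev.gene_id, []).append(c)

    internal_constructs = {"more": [], "less": []}
    n_unplaceable = 0
    for direction, es in (("more", more), ("less", less)):
        for gid in sorted({ev.gene_id for ev in es}):
            gene = annotation.genes[gid]
            ctrl = sample_internal_control(gene, per_gene[gid], seed=cfg.seed)
            if ctrl is None:
                n_unplaceable += 1
            else:
                internal_constructs[direction].append(ctrl)

    ctrl_cfg = ControlConfig(n_external=n_external, seed=cfg.seed)
    external_genes = select_external_control_genes(
        bundle.expression, list(filtered.values()), annotation, bundle.mane, ctrl_cfg
    )
    external_constructs = sample_external_controls(
        external_genes, annotation, bundle.mane, seed=cfg.seed
    )

    ss_model = train_splice_site_model(annotation)
    bp_model = default_branch_point_model()

    def featurize(constructs: list[EIEIEConstruct]) -> pd.DataFrame:
        fvs = []
        for c in constructs:
            extract_sequences(c, annotation)
            fvs.append(compute_features(c, ss_model, bp_model))
        return features_to_frame(fvs)

    frames = {
        "more": featurize(event_constructs["more"]),
        "less": featurize(event_constructs["less"]),
        "internal_more": featurize(internal_constructs["more"]),
        "internal_less": featurize(internal_constructs["less"]),
        "external": featurize(external_constructs),
    }
    summary = build_summary(
        frames["more"],
        frames["less"],
        {"more": frames["internal_more"], "less": frames["internal_less"]},
        frames["external"],
        alpha=alpha,
    )
    return PipelineResult(
        bundle=bundle,
        filtered=filtered,
        more_skipped=more,
        less_skipped=less,
        event_constructs=event_constructs,
        internal_constructs=internal_constructs,
        external_constructs=external_constructs,
        feature_frames=frames,
        summary=summary,
        external_gene_ids=external_genes,
        n_internal_unplaceable=n_unplaceable,
    )
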