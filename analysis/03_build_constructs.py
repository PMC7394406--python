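"""Build event and control E-I-E-I-E constructs.

Event constructs come from the filtered SE rows; internal controls are one
random non-overlapping window per event gene from its reference transcript;
external controls are one random window from each of the top-expressed,
non-mitochondrial, non-differentially-spliced, MANE-matched genes. Writes a
BED12-like table of every construct under results/.
"""

import argparse
from pathlib import Path

from skipfeat.annotation import load_annotation, write_constructs_tsv
from skipfeat.controls import (
    ControlConfig,
    ExpressionTable,
    ManeSet,
    build_event_construct,
    sample_external_controls,
    sample_internal_control,
    select_external_control_genes,
)
from skipfeat.events import filter_events, read_rmats, split_by_direction


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--bundle", type=Path, default=None)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--n-external", type=int, default=100)
    args = ap.parse_args()
    d = args.bundle or Path("scratch") / f"sim_seed{args.seed}"
    args.results.mkdir(parents=True, exist_ok=True)

    ann = load_annotation(d / "annotation.gtf", d / "genome.fa")
    raw = read_rmats({cls: d / f"{cls}.MATS.JC.txt"
                      for cls in ("SE", "A3SS", "A5SS", "MXE", "RI")})
    filtered = {cls: filter_events(es) for cls, es in raw.items()}
    more, less = split_by_direction(filtered["SE"])

    constructs = []
    per_gene = {}
    for es in (more, less):
        for ev in es:
            c = build_event_construct(ev)
            constructs.append(c)
            per_gene.setdefault(ev.gene_id, []).append(c)

    n_unplaceable = 0
    for gid in sorted(per_gene):
        ctrl = sample_internal_control(ann.genes[gid], per_gene[gid], seed=args.seed)
        if ctrl is None:
            n_unplaceable += 1
        else:
            constructs.append(ctrl)

    expr = ExpressionTable.read_tsv(d / "expression.tsv")
    mane = ManeSet.read_tsv(d / "mane.tsv")
    cfg = ControlConfig(n_external=args.n_external, seed=args.seed)
    ext_genes = select_external_control_genes(
        expr, list(filtered.values()), ann, mane, cfg)
    externals = sample_external_controls(ext_genes, ann, mane, seed=args.seed)
    constructs.extend(externals)

    out = args.results / "constructs.tsv"
    write_constructs_tsv(constructs, out)
    n_event = len(more) + len(less)
    print(f"event constructs: {n_event} "
          f"({len(more)} more skipped, {len(less)} less skipped)")
    print(f"internal controls: {len(per_gene) - n_unplaceable} "
          f"({n_unplaceable} genes with no valid non-overlapping window)")
    print(f"external controls: {len(externals)} from {len(ext_genes)} selected genes")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
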