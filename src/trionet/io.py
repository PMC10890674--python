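"""File formats: trio-site tables, edge lists, GMT collections, gene lists.

All formats are plain text. Lines starting with ``#`` are provenance/comment
lines and are ignored by every reader; generated files carry a provenance
header recording the package version, the seed and the generator parameters,
so a written file always documents how it was produced.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple, Union

import pandas as pd
import yaml

from trionet.enrichment import AnnotationSet
from trionet.network_search import GenomicEvent, LikelihoodNetwork
from trionet.trio_denovo import MEMBERS, CandidateSite, SiteReadData

PathLike = Union[str, Path]

__all__ = [
    "provenance_header",
    "read_trio_sites",
    "write_trio_sites",
    "read_edge_list",
    "write_edge_list",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "write_gene_list",
    "read_events",
    "write_events",
    "read_labeled_scores",
    "write_labeled_scores",
    "write_candidates",
    "read_config",
    "write_run_summary",
]


def provenance_header(seed=None, **params) -> str:
    from trionet import __version__

    parts = [f"# trionet v{__version__}"]
    if seed is not None:
        parts.append(f"# seed={seed}")
    for k in sorted(params):
        parts.append(f"# {k}={params[k]}")
    return "\n".join(parts) + "\n"


def _write_text(path: PathLike, header: str, body: str) -> None:
    Path(path).write_text(header + body)


# -- trio sites -------------------------------------------------------------

_SITE_COLUMNS = ["site_id", "chrom", "pos"] + [
    f"{m}_{f}" for m in MEMBERS for f in ("depth", "alt")
]


def write_trio_sites(
    sites: Sequence[SiteReadData], path: PathLike, header: str = ""
) -> None:
    rows = [
        dict(
            site_id=s.site_id, chrom=s.chrom, pos=s.pos,
            **{f"{m}_depth": s.depth[m] for m in MEMBERS},
            **{f"{m}_alt": s.alt_count[m] for m in MEMBERS},
        )
        for s in sites
    ]
    body = pd.DataFrame(rows, columns=_SITE_COLUMNS).to_csv(sep="\t", index=False)
    _write_text(path, header, body)


def read_trio_sites(path: PathLike) -> List[SiteReadData]:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trio-site table missing column(s): {missing}")
    return [
        SiteReadData(
            site_id=str(r.site_id), chrom=str(r.chrom), pos=int(r.pos),
            depth={m: int(getattr(r, f"{m}_depth")) for m in MEMBERS},
            alt_count={m: int(getattr(r, f"{m}_alt")) for m in MEMBERS},
        )
        for r in df.itertuples(index=False)
    ]


# -- weighted edge lists ----------------------------------------------------

def write_edge_list(
    network: LikelihoodNetwork, path: PathLike, header: str = ""
) -> None:
    lines = ["geneA\tgeneB\tweight"]
    canon = sorted(
        (min(a, b), max(a, b), d["weight"])
        for a, b, d in network.graph.edges(data=True)
    )
    for a, b, w in canon:
        lines.append(f"{a}\t{b}\t{w!r}")
    # isolated nodes are part of the gene universe; keep them on record
    isolated = sorted(n for n in network.graph.nodes if network.graph.degree(n) == 0)
    extra = "".join(f"#node\t{n}\n" for n in isolated)
    _write_text(path, header, "\n".join(lines) + "\n" + extra)


def read_edge_list(path: PathLike) -> LikelihoodNetwork:
    edges: List[Tuple[str, str, float]] = []
    isolated: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#node\t"):
                isolated.append(line.split("\t", 1)[1])
                continue
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[:3] == ["geneA", "geneB", "weight"]:
                continue
            if len(parts) < 3:
                raise ValueError(f"malformed edge line: {line!r}")
            edges.append((parts[0], parts[1], float(parts[2])))
    net = LikelihoodNetwork.from_edges(edges)
    net.graph.add_nodes_from(isolated)
    return net


# -- GMT annotation collections --------------------------------------------

def write_gmt(
    collection: Sequence[AnnotationSet], path: PathLike, header: str = ""
) -> None:
    lines = [
        "\t".join([t.term_id, f"{t.ontology}|{t.term_name}"] + sorted(t.genes))
        for t in collection
    ]
    _write_text(path, header, "\n".join(lines) + ("\n" if lines else ""))


def read_gmt(path: PathLike) -> List[AnnotationSet]:
    out: List[AnnotationSet] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line.split(chr(9))[0]!r}")
            desc = parts[1]
            ontology, _, name = desc.partition("|")
            if not name:
                ontology, name = "NA", desc
            out.append(
                AnnotationSet(
                    term_id=parts[0], term_name=name, ontology=ontology,
                    genes=frozenset(parts[2:]),
                )
            )
    return out


# -- plain gene lists -------------------------------------------------------

def write_gene_list(genes: Iterable[str], path: PathLike, header: str = "") -> None:
    _write_text(path, header, "".join(f"{g}\n" for g in genes))


def read_gene_list(path: PathLike) -> List[str]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


# -- genomic events ---------------------------------------------------------

def write_events(
    events: Sequence[GenomicEvent], path: PathLike, header: str = ""
) -> None:
    lines = ["event_id\ttype\tgenes"]
    for e in events:
        lines.append(f"{e.event_id}\t{e.variant_type}\t{','.join(sorted(e.genes))}")
    _write_text(path, header, "\n".join(lines) + "\n")


def read_events(path: PathLike) -> List[GenomicEvent]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("event_id", "type", "genes"):
        if col not in df.columns:
            raise ValueError(f"events table missing column {col!r}")
    return [
        GenomicEvent(
            event_id=str(r.event_id),
            variant_type=str(r.type),
            genes=frozenset(str(r.genes).split(",")),
        )
        for r in df.itertuples(index=False)
    ]


# -- labelled scores --------------------------------------------------------

def write_labeled_scores(
    scores: Sequence[Tuple[float, str]], path: PathLike, header: str = ""
) -> None:
    body = "log_bf\tlabel\n" + "".join(f"{s!r}\t{lab}\n" for s, lab in scores)
    _write_text(path, header, body)


def read_labeled_scores(path: PathLike) -> List[Tuple[float, str]]:
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    if "log_bf" not in df.columns or "label" not in df.columns:
        raise ValueError("labelled-score table needs columns log_bf, label")
    return [(float(r.log_bf), str(r.label)) for r in df.itertuples(index=False)]


# -- candidate output -------------------------------------------------------

def write_candidates(
    candidates: Sequence[CandidateSite], path: PathLike, header: str = ""
) -> None:
    rows = []
    for c in candidates:
        rows.append(
            dict(
                site_id=c.site.site_id, chrom=c.site.chrom, pos=c.site.pos,
                genotype_class=c.genotype_class,
                log_posterior_odds=c.log_posterior_odds,
                log_bf="" if c.log_bf is None else c.log_bf,
                passed_filters=int(c.passed_filters),
                min_depth=c.min_depth,
            )
        )
    body = pd.DataFrame(rows).to_csv(sep="\t", index=False)
    _write_text(path, header, body)


# -- config and run summaries ----------------------------------------------

def read_config(path: PathLike) -> Dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def write_run_summary(path: PathLike, **fields) -> None:
    from trionet import __version__

    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (frozenset, set, tuple)):
            return sorted(o) if isinstance(o, (frozenset, set)) else list(o)
        if hasattr(o, "item"):
            return o.item()
        return str(o)

    payload = {"version": __version__, **fields}
    Path(path).write_text(json.dumps(payload, indent=2, default=default) + "\n")
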