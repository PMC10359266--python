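"""Full two-structure comparison: census → alignment → superposition →
H-bond graphs → difference graph → key distances → cavities/tunnel.

Every quantitative statement of the comparison comes from exactly one
upstream operation, and the report regenerates deterministically from
the same inputs and configuration (the JSON form carries no timestamps).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import hbond, pore, structure, superpose
from .correspondence import structure_residue_map
from .structure import Structure

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class CompareConfig:
    """All cutoffs and probes of the comparison, with literature defaults.

    Residue pairs of interest default to the channelrhodopsin key
    contacts (Asp116–Arg244, Ser73–Asp116, Tyr106–His225,
    Tyr222–Trp102, Tyr222–Gln218) and the displacement probe to the
    Val66 Cα; both are plain sequence numbers and should be replaced
    when comparing other proteins.
    """

    hbond_cutoff: float = 4.0
    water_policy: str = "include_water_water"
    grid_spacing: float = 0.5
    surface_probe: float = 1.4
    tunnel_probe: float = 0.9
    chain_a: str | None = None
    chain_b: str | None = None
    residue_pairs: list[tuple[int, int]] = field(
        default_factory=lambda: [(116, 244), (73, 116), (106, 225), (222, 102), (222, 218)]
    )
    displacement_residues: list[int] = field(default_factory=lambda: [66])
    displacement_atom: str = "CA"
    include_pore: bool = True
    seed_point: str | tuple[float, float, float] = "auto"
    schiff_residue: int = 233
    aromatic_residues: tuple[int, ...] = (102, 210, 221, 222)
    grid_padding: float = 6.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CompareConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls()
        for k, v in data.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown config key {k!r}")
            setattr(cfg, k, v)
        cfg.residue_pairs = [tuple(p) for p in cfg.residue_pairs]
        return cfg


@dataclass
class ComparisonReport:
    structures: dict
    census: dict
    alignment: dict
    superposition: dict
    displacements: dict
    graphs: dict
    difference: dict
    distances: dict
    pore: dict
    config: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True, default=_jsonable)

    def to_markdown(self) -> str:
        lines = [
            f"# Comparison: {self.structures['a']} vs {self.structures['b']}",
            "",
            "## Entity census (per structure, whole model)",
        ]
        for tag in ("a", "b"):
            c = self.census[tag]["all"]
            lines.append(
                f"- {tag.upper()}: " + ", ".join(f"{k}={v}" for k, v in sorted(c.items()) if v)
            )
        a = self.alignment
        lines += [
            "",
            f"## Sequence: identity {a['identity_pct']:.1f} %, "
            f"similarity {a['similarity_pct']:.1f} %, {a['n_pairs']} mapped residues",
            "",
            "## Superposition",
        ]
        for k, v in sorted(self.superposition.items()):
            lines.append(f"- RMSD ({k}): {v:.3f} Å")
        lines += ["", "## Per-residue displacements (Å, common Cα frame)"]
        for k, v in sorted(self.displacements.items()):
            lines.append(f"- {k}: {v:.2f}")
        lines += ["", "## H-bond graphs"]
        for tag in ("a", "b"):
            s = self.graphs[tag]
            lines.append(
                f"- {tag.upper()}: {s['total_edges']} H-bonds, "
                f"{s['water_mediated_edges']} water-mediated, {s['strong_edges']} strong"
            )
        d = self.difference
        lines += [
            "",
            f"## Difference graph: {d['n_conserved']} conserved, "
            f"{d['n_unique_a']} unique to A, {d['n_unique_b']} unique to B",
            "",
            "## Key residue distances (Å, min over polar side-chain heteroatoms)",
        ]
        for k, v in sorted(self.distances.items()):
            val = "n/a" if v is None else f"{v:.2f}"
            lines.append(f"- {k}: {val}")
        if self.pore:
            lines += ["", "## Cavities and tunnel"]
            for tag in ("a", "b"):
                p = self.pore[tag]
                lines.append(
                    f"- {tag.upper()}: {p['n_cavities']} cavities "
                    f"(largest {p['largest_cavity_volume']:.0f} Å³); "
                    f"tunnel to bulk: {p['tunnel_found']}"
                    + (
                        f" (bottleneck {p['bottleneck_radius']:.2f} Å)"
                        if p["tunnel_found"]
                        else ""
                    )
                )
        return "\n".join(lines) + "\n"


def _jsonable(obj):
    import numpy as np

    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise StageError(name, exc) from exc

        return wrapper

    return deco


def _load(obj, dialect: str = "auto") -> Structure:
    if isinstance(obj, Structure):
        return obj
    return structure.parse_structure(obj, dialect)


def _find_by_num(s: Structure, chain: str, num: int):
    for r in s.protein_residues(chain):
        if r.seq_num == num:
            return r
    return None


def run_compare(
    a, b, config: CompareConfig | None = None
) -> ComparisonReport:
    """Run the full comparison of two structures (paths or Structures)."""
    cfg = config or CompareConfig()
    logger.info("compare config: %s", asdict(cfg))

    s_a = _load(a)
    s_b = _load(b)
    chain_a = cfg.chain_a or s_a.protein_chains()[0]
    chain_b = cfg.chain_b or s_b.protein_chains()[0]

    census = _stage("census")(_census)(s_a, s_b)
    rmap = _stage("alignment")(structure_residue_map)(s_a, s_b, chain_a, chain_b)
    alignment = {
        "identity_pct": rmap.identity_pct,
        "similarity_pct": rmap.similarity_pct,
        "n_pairs": len(rmap),
        "n_unmatched_a": len(rmap.unmatched_a),
        "n_unmatched_b": len(rmap.unmatched_b),
    }

    sup = _stage("superposition")(_superpositions)(s_a, s_b, rmap)
    frame = superpose.paired_superpose(s_a, s_b, rmap, "CA_only")
    displacements = _stage("displacement")(_displacements)(
        s_a, s_b, rmap, chain_a, cfg, frame
    )

    graphs, diff = _stage("hbond_graphs")(_graphs)(s_a, s_b, rmap, cfg)
    distances = _stage("distances")(_distances)(s_a, s_b, chain_a, chain_b, cfg)
    pore_out = (
        _stage("pore")(_pore)(s_a, s_b, cfg) if cfg.include_pore else {}
    )

    return ComparisonReport(
        structures={"a": s_a.id, "b": s_b.id},
        census=census,
        alignment=alignment,
        superposition=sup,
        displacements=displacements,
        graphs=graphs,
        difference=diff,
        distances=distances,
        pore=pore_out,
        config=asdict(cfg),
    )


def _census(s_a: Structure, s_b: Structure) -> dict:
    out = {}
    for tag, s in (("a", s_a), ("b", s_b)):
        cls = structure.classify_entities(s)
        entry = {"all": dict(structure.entity_census(s, None, cls))}
        for k in range(s.n_protomers()):
            entry[f"protomer_{k}"] = dict(structure.entity_census(s, k, cls))
        out[tag] = entry
    return out


def _superpositions(s_a, s_b, rmap) -> dict:
    return {
        "ca_protomer": superpose.paired_rmsd(s_a, s_b, rmap, "CA_only"),
        "all_heavy_protomer": superpose.paired_rmsd(s_a, s_b, rmap, "all_heavy"),
    }


def _displacements(s_a, s_b, rmap, chain_a, cfg, frame) -> dict:
    out = {}
    for num in cfg.displacement_residues:
        r = _find_by_num(s_a, chain_a, num)
        if r is None:
            out[f"{num}"] = None
            continue
        out[f"{r.comp_id}{num}"] = superpose.residue_displacement(
            s_a, s_b, rmap, r.key, cfg.displacement_atom, frame
        )
    return out


def _graphs(s_a, s_b, rmap, cfg) -> tuple[dict, dict]:
    g_a = hbond.hbond_graph(s_a, cfg.hbond_cutoff, water_policy=cfg.water_policy)
    g_b = hbond.hbond_graph(s_b, cfg.hbond_cutoff, water_policy=cfg.water_policy)
    diff = hbond.difference_graph(g_a, g_b, rmap)
    graphs = {
        "a": hbond.summarize_graph(g_a),
        "b": hbond.summarize_graph(g_b),
        "edges_a": hbond.graph_edge_list_json(g_a),
        "edges_b": hbond.graph_edge_list_json(g_b),
    }
    diff_out = {
        "n_conserved": len(diff.conserved_edges),
        "n_unique_a": len(diff.unique_a_edges),
        "n_unique_b": len(diff.unique_b_edges),
        "conserved_edges": diff.conserved_edges,
        "unique_a_edges": diff.unique_a_edges,
        "unique_b_edges": diff.unique_b_edges,
    }
    return graphs, diff_out


def _distances(s_a, s_b, chain_a, chain_b, cfg) -> dict:
    out = {}
    for tag, s, chain in (("a", s_a, chain_a), ("b", s_b, chain_b)):
        for n1, n2 in cfg.residue_pairs:
            r1 = _find_by_num(s, chain, n1)
            r2 = _find_by_num(s, chain, n2)
            label = f"{tag}:{n1}-{n2}"
            if r1 is None or r2 is None:
                out[label] = None
                continue
            try:
                out[f"{tag}:{r1.comp_id}{n1}-{r2.comp_id}{n2}"] = (
                    hbond.min_sidechain_distance(s, r1.key, r2.key)
                )
            except ValueError:
                out[label] = None
    return out


def _pore(s_a, s_b, cfg) -> dict:
    out = {}
    for tag, s in (("a", s_a), ("b", s_b)):
        grid = pore.rasterize(s, cfg.grid_spacing, cfg.grid_padding)
        cav = pore.find_cavities(grid, cfg.surface_probe)
        if cfg.seed_point == "auto":
            seed = pore.auto_seed(s, cfg.schiff_residue, cfg.aromatic_residues)
        else:
            seed = tuple(cfg.seed_point)
        tun = pore.tunnel_search(
            grid, seed, cfg.tunnel_probe, cfg.surface_probe, bulk=cav.bulk
        )
        out[tag] = {
            "n_cavities": len(cav.cavities),
            "largest_cavity_volume": cav.cavities[0].volume if cav.cavities else 0.0,
            "cavity_volumes": [c.volume for c in cav.cavities[:10]],
            "tunnel_found": tun is not None,
            "bottleneck_radius": tun.bottleneck_radius if tun else None,
            "seed": list(map(float, seed)) if not isinstance(seed, str) else seed,
        }
    return out
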