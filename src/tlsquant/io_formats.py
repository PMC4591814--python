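"""Readers and writers for the interchange formats.

Lane tables travel as comma-separated CSV (UTF-8, mandatory header, "."
decimal) with one row per band; band positions are absolute product
lengths in nt — gels are read in nt — and are converted to N indices at
load time using the substrate registry. Outputs are TSV. Substrates,
extension profiles and simulation configs are JSON; substrates also export
to FASTA (plain ACGT letters, lesion noted in the description line).

Readers reject rather than coerce: every error names the offending
column, row or field. Write -> read round trips are identity for lanes,
substrates and configs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigurationError, SchemaError
from .extension_model import ALL_DNTPS, ExtensionProfile, ReactionConditions
from .quantify import BypassSummary, Lane, PositionStats, format_percent
from .substrates import LesionKind, Oligo, Substrate, assemble_substrate

logger = logging.getLogger(__name__)

LANE_COLUMNS = [
    "lane_id",
    "enzyme",
    "substrate",
    "time_min",
    "replicate",
    "band_length_nt",
    "intensity",
]

SUMMARY_COLUMNS = [
    "enzyme",
    "substrate",
    "bypass_pct",
    "bypass_sd_pct",
    "insertion_pct",
    "insertion_sd_pct",
    "extension_pct",
    "extension_sd_pct",
    "efficiency_pct",
    "efficiency_sd_pct",
    "n_lanes",
]


# ---------------------------------------------------------------------------
# lane tables


def read_lane_table(
    path: str | Path, substrate_registry: Mapping[str, Substrate]
) -> list[Lane]:
    """Load a lane CSV into :class:`Lane` objects (zero-filling absent bands).

    Raises :class:`SchemaError` on a missing column, unknown substrate,
    band length outside [n0, n0+K], duplicate (lane_id, band_length_nt), or
    inconsistent per-lane metadata.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in LANE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    if df.empty:
        raise SchemaError(f"{path}: no band rows")
    if (df["intensity"] < 0).any():
        row = int(df.index[df["intensity"] < 0][0]) + 2  # header is line 1
        raise SchemaError(f"{path}: negative intensity at line {row}")

    dup = df.duplicated(subset=["lane_id", "band_length_nt"])
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise SchemaError(f"{path}: duplicate (lane_id, band_length_nt) at line {row}")

    lanes: list[Lane] = []
    zero_filled = 0
    for lane_id, grp in df.groupby("lane_id", sort=True):
        sub_names = grp["substrate"].unique()
        if len(sub_names) != 1:
            raise SchemaError(f"{path}: lane {lane_id!r} mixes substrates")
        sub_name = str(sub_names[0])
        if sub_name not in substrate_registry:
            raise SchemaError(f"{path}: unknown substrate {sub_name!r}")
        sub = substrate_registry[sub_name]
        for col in ("enzyme", "time_min", "replicate"):
            if grp[col].nunique() != 1:
                raise SchemaError(f"{path}: lane {lane_id!r} has inconsistent {col}")
        intensities = np.zeros(sub.k + 1)
        for idx, row in grp.iterrows():
            length = int(row["band_length_nt"])
            if not sub.n0 <= length <= sub.n0 + sub.k:
                raise SchemaError(
                    f"{path}: band_length_nt {length} outside "
                    f"[{sub.n0}, {sub.n0 + sub.k}] at line {int(idx) + 2}"
                )
            intensities[length - sub.n0] = float(row["intensity"])
        zero_filled += sub.k + 1 - len(grp)
        lanes.append(
            Lane(
                lane_id=str(lane_id),
                enzyme=str(grp["enzyme"].iloc[0]),
                substrate_name=sub_name,
                time_min=float(grp["time_min"].iloc[0]),
                replicate=int(grp["replicate"].iloc[0]),
                intensities=intensities,
            )
        )
    logger.info(
        "read %d lanes (%d band rows, %d positions zero-filled) from %s",
        len(lanes), len(df), zero_filled, path,
    )
    return lanes


def write_lanes(
    lanes: Sequence[Lane],
    path: str | Path,
    substrate_registry: Mapping[str, Substrate],
) -> None:
    """Write lanes as a band-per-row CSV (all K+1 bands, zeros included, so
    the write -> read round trip is exact)."""
    if not lanes:
        raise SchemaError("no lanes to write")
    rows = []
    for ln in lanes:
        if ln.substrate_name not in substrate_registry:
            raise SchemaError(f"unknown substrate {ln.substrate_name!r}")
        n0 = substrate_registry[ln.substrate_name].n0
        for n, inten in enumerate(ln.intensities):
            rows.append(
                (
                    ln.lane_id,
                    ln.enzyme,
                    ln.substrate_name,
                    ln.time_min,
                    ln.replicate,
                    n0 + n,
                    repr(float(inten)),
                )
            )
    pd.DataFrame(rows, columns=LANE_COLUMNS).to_csv(path, index=False)
    logger.info("wrote %d lanes to %s", len(lanes), path)


# ---------------------------------------------------------------------------
# statistics tables


def write_position_stats(
    stats: Sequence[PositionStats], path: str | Path
) -> None:
    """Long-format TSV: lane_id, N, statistic, value, defined_flag."""
    if not stats:
        raise SchemaError("no position statistics to write")
    domains = {
        "termination": lambda n, k: 0 <= n <= k,
        "insertion": lambda n, k: 1 <= n <= k,
        "extension": lambda n, k: 0 <= n <= k - 1,
        "bypass": lambda n, k: 1 <= n <= k - 1,
    }
    rows = []
    for st in stats:
        undef = {(name, n) for name, n, _ in st.undefined}
        for name in ("termination", "insertion", "extension", "bypass"):
            arr = getattr(st, name)
            for n in range(st.k + 1):
                if not domains[name](n, st.k):
                    continue
                defined = (name, n) not in undef
                value = f"{arr[n]:.6f}" if defined else ""
                rows.append((st.lane_id, n, name, value, defined))
    pd.DataFrame(
        rows, columns=["lane_id", "N", "statistic", "value", "defined_flag"]
    ).to_csv(path, sep="\t", index=False)


def _pct(value: Optional[float]) -> str:
    return "" if value is None else format_percent(100.0 * value)


def write_summary(summaries: Sequence[BypassSummary], path: str | Path) -> None:
    """Replicate-summary TSV, one row per enzyme x substrate.

    Probabilities are percent with one decimal (round half up); the
    efficiency columns stay empty for summaries without an undamaged
    partner. SD columns are labelled as SD, not "±".
    """
    if not summaries:
        raise SchemaError("no summaries to write")
    rows = []
    for s in summaries:
        rows.append(
            (
                s.enzyme,
                s.substrate_name,
                _pct(s.bypass_mean),
                _pct(s.bypass_sd),
                _pct(s.insertion_mean),
                _pct(s.insertion_sd),
                _pct(s.extension_mean),
                _pct(s.extension_sd),
                "" if s.efficiency_pct is None else format_percent(s.efficiency_pct),
                "" if s.efficiency_sd_pct is None else format_percent(s.efficiency_sd_pct),
                s.n_lanes,
            )
        )
    pd.DataFrame(rows, columns=SUMMARY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_summary(path: str | Path) -> list[BypassSummary]:
    """Parse a summary TSV back into :class:`BypassSummary` objects
    (percent columns become fractions; empty efficiency stays None)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    out = []
    for _, r in df.iterrows():
        out.append(
            BypassSummary(
                enzyme=r["enzyme"],
                substrate_name=r["substrate"],
                lesion_n=0,
                n_lanes=int(r["n_lanes"]),
                insertion_mean=float(r["insertion_pct"]) / 100,
                insertion_sd=float(r["insertion_sd_pct"]) / 100,
                extension_mean=float(r["extension_pct"]) / 100,
                extension_sd=float(r["extension_sd_pct"]) / 100,
                bypass_mean=float(r["bypass_pct"]) / 100,
                bypass_sd=float(r["bypass_sd_pct"]) / 100,
                efficiency_pct=float(r["efficiency_pct"]) if r["efficiency_pct"] else None,
                efficiency_sd_pct=float(r["efficiency_sd_pct"]) if r["efficiency_sd_pct"] else None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# substrates (JSON + FASTA)


def substrate_to_dict(substrate: Substrate) -> dict:
    doc = {
        "name": substrate.name,
        "primer": substrate.primer.sequence,
        "template_5to3": substrate.template.sequence,
        "lesions": [
            {"pos": pos, "kind": kind.value}
            for pos, kind in sorted(substrate.template.lesions.items())
        ],
    }
    if substrate.downstream is not None:
        doc["downstream"] = substrate.downstream.sequence
    return doc


def substrate_from_dict(doc: Mapping) -> Substrate:
    for key in ("name", "primer", "template_5to3"):
        if key not in doc:
            raise SchemaError(f"substrate document: missing field {key!r}")
    lesions = {}
    for entry in doc.get("lesions", []):
        if "pos" not in entry or "kind" not in entry:
            raise SchemaError("substrate document: lesion entry needs pos and kind")
        lesions[int(entry["pos"])] = LesionKind(entry["kind"])
    template = Oligo("template", doc["template_5to3"], lesions)
    downstream = doc.get("downstream")
    return assemble_substrate(
        Oligo("primer", doc["primer"]),
        template,
        Oligo("downstream", downstream) if downstream else None,
        name=doc["name"],
    )


def write_substrate_json(substrate: Substrate, path: str | Path) -> None:
    Path(path).write_text(json.dumps(substrate_to_dict(substrate), indent=2) + "\n")


def read_substrate_json(path: str | Path) -> Substrate:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: malformed JSON at line {exc.lineno}") from exc
    return substrate_from_dict(doc)


def write_substrate_fasta(substrate: Substrate, path: str | Path) -> None:
    """FASTA export of the annealed strands (60-column wrapping); lesion
    annotations go in the description line, the letters stay plain ACGT."""
    records = []
    for role, oligo in (
        ("primer", substrate.primer),
        ("template", substrate.template),
        ("downstream", substrate.downstream),
    ):
        if oligo is None:
            continue
        desc = f"{role} 5'->3'"
        if oligo.lesions:
            notes = ",".join(
                f"{kind.value}@{pos}" for pos, kind in sorted(oligo.lesions.items())
            )
            desc += f" lesions:{notes}"
        records.append(
            SeqRecord(Seq(oligo.sequence), id=f"{substrate.name}|{role}", description=desc)
        )
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# simulation configs


def profile_to_dict(profile: ExtensionProfile) -> dict:
    return {
        "label": profile.label,
        "e_correct": [float(x) for x in profile.e_correct],
        "e_mis": [float(x) for x in profile.e_mis],
        "displacement_factor": profile.displacement_factor,
    }


def write_profile_json(profile: ExtensionProfile, path: str | Path) -> None:
    Path(path).write_text(json.dumps(profile_to_dict(profile), indent=2) + "\n")


def config_to_dict(
    substrate: Substrate | str,
    profile: ExtensionProfile,
    conditions: ReactionConditions,
) -> dict:
    return {
        "substrate": substrate if isinstance(substrate, str) else substrate_to_dict(substrate),
        "profile": profile_to_dict(profile),
        "conditions": {
            "dNTPs": sorted(conditions.dntps),
            "times": list(conditions.times),
            "engagement_rate": conditions.engagement_rate,
            "molecules": conditions.molecules,
            "noise_sigma_mult": conditions.noise_sigma_mult,
            "background": conditions.background,
            "replicates": conditions.replicates,
            "single_hit": conditions.single_hit,
        },
        "seed": conditions.seed,
    }


def write_config(
    substrate: Substrate | str,
    profile: ExtensionProfile,
    conditions: ReactionConditions,
    path: str | Path,
) -> None:
    Path(path).write_text(
        json.dumps(config_to_dict(substrate, profile, conditions), indent=2) + "\n"
    )


def read_config(
    path: str | Path,
    substrate_registry: Optional[Mapping[str, Substrate]] = None,
) -> tuple[Substrate, ExtensionProfile, ReactionConditions]:
    """Load a simulation config; the substrate may be inline or a registry
    name. Validates vector lengths against the substrate's K."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: malformed JSON at line {exc.lineno}") from exc
    for key in ("substrate", "profile", "conditions", "seed"):
        if key not in doc:
            raise SchemaError(f"{path}: missing field {key!r}")
    sub_doc = doc["substrate"]
    if isinstance(sub_doc, str):
        if not substrate_registry or sub_doc not in substrate_registry:
            raise SchemaError(f"{path}: substrate {sub_doc!r} not in registry")
        substrate = substrate_registry[sub_doc]
    else:
        substrate = substrate_from_dict(sub_doc)
    pdoc = doc["profile"]
    for key in ("e_correct", "e_mis"):
        if key not in pdoc:
            raise SchemaError(f"{path}: profile missing field {key!r}")
        if len(pdoc[key]) != substrate.k:
            raise SchemaError(
                f"{path}: profile field {key!r} has length {len(pdoc[key])}, "
                f"expected K={substrate.k}"
            )
    profile = ExtensionProfile(
        label=pdoc.get("label", "profile"),
        e_correct=pdoc["e_correct"],
        e_mis=pdoc["e_mis"],
        displacement_factor=float(pdoc.get("displacement_factor", 1.0)),
    )
    cdoc = doc["conditions"]
    try:
        conditions = ReactionConditions(
            seed=int(doc["seed"]),
            dntps=frozenset(cdoc.get("dNTPs", sorted(ALL_DNTPS))),
            times=tuple(cdoc.get("times", (2.0, 4.0, 6.0))),
            engagement_rate=float(cdoc.get("engagement_rate", 0.05)),
            molecules=int(cdoc.get("molecules", 20_000)),
            noise_sigma_mult=float(cdoc.get("noise_sigma_mult", 0.05)),
            background=float(cdoc.get("background", 0.0)),
            replicates=int(cdoc.get("replicates", 2)),
            single_hit=bool(cdoc.get("single_hit", False)),
        )
    except ConfigurationError as exc:
        raise SchemaError(f"{path}: invalid conditions: {exc}") from exc
    return substrate, profile, conditions
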