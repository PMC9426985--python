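"""Delimited-text input/output and the run manifest.

All tables are comma-separated UTF-8 with a mandatory header row and period
decimals.  A run manifest (YAML) names every input file and carries the
analysis options; paths are resolved relative to the manifest's directory.

The reader is tolerant of extra columns (warned and ignored) but strict about
missing required columns, malformed values and dangling identifiers, which
are reported with file and line.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .costing import ServiceUnitCost, pool_from_expenditure
from .errors import MissingInputError
from .fixtures import FacilityInputs
from .national import extrapolate_national, facility_metrics, summarize_type
from .pipeline import BundleAnalysis, FacilityAnalysis, analyze_facility
from .reporting import rank_services
from .synthetic import SyntheticBundle
from .types import (
    AdjustmentFactors,
    Cadre,
    CareType,
    EpidemiologyEntry,
    FacilityDataset,
    FacilityType,
    FacilityTypeCensus,
    Issue,
    ItemCategory,
    RateKind,
    ResourceItem,
    ServiceDefinition,
    TreatmentProtocol,
    round_half_up,
    validate_dataset,
)

__all__ = [
    "RunManifest",
    "InputBundle",
    "load_manifest",
    "read_inputs",
    "run_pipeline",
    "write_bundle_inputs",
    "write_unit_costs",
    "write_national",
    "render_aligned",
]

log = logging.getLogger("bphs_costing")

_TABLE_COLUMNS = {
    "cadres": ["cadre_id", "name", "annual_remuneration", "annual_available_minutes", "is_technical"],
    "items": ["item_id", "name", "category", "unit_price", "donated"],
    "services": ["service_id", "name", "program", "care_type", "in_bphs"],
    "protocols": ["service_id", "resource_kind", "ref_id", "amount"],
    "epidemiology": ["service_id", "annual_rate", "rate_kind", "source_note"],
    "facilities": ["facility_id", "facility_type", "province", "catchment_population"],
    "staffing": ["facility_id", "cadre_id", "headcount"],
    "utilization": ["facility_id", "service_id", "annual_count"],
    "expenditure": ["facility_id", "line_item", "amount"],
    "census": ["facility_type", "n_facilities"],
}
_OPTIONAL_TABLES = {"epidemiology", "census"}


class RunManifest(BaseModel):
    """Named input files plus analysis options for one pipeline run."""

    model_config = ConfigDict(frozen=True)

    base_dir: Path
    inputs: dict[str, Path]
    population_mode: str = "actual"  # actual | normative
    normative_population: dict[FacilityType, float] = Field(default_factory=dict)
    adjustment: AdjustmentFactors | None = None
    national_population: float | None = None
    top_n: int = 10
    out_dir: Path = Path("reports")
    report_format: str = "csv"  # csv | aligned
    log_level: str = "INFO"

    def path(self, table: str) -> Path:
        p = self.inputs[table]
        return p if p.is_absolute() else self.base_dir / p


def load_manifest(path: str | Path) -> RunManifest:
    path = Path(path)
    raw: dict[str, Any] = yaml.safe_load(path.read_text())
    options = raw.get("options", {})
    adj = options.get("adjustment")
    manifest = RunManifest(
        base_dir=path.parent,
        inputs={k: Path(v) for k, v in raw.get("inputs", {}).items()},
        population_mode=options.get("population_mode", "actual"),
        normative_population={
            FacilityType(k): float(v)
            for k, v in options.get("normative_population", {}).items()
        },
        adjustment=(
            AdjustmentFactors(
                other_provider_share={
                    FacilityType(k): float(v)
                    for k, v in adj.get("other_provider_share", {}).items()
                },
                non_access_share=float(adj.get("non_access_share", 0.0)),
            )
            if adj
            else None
        ),
        national_population=options.get("national_population"),
        top_n=int(options.get("top_n", 10)),
        out_dir=Path(options.get("out_dir", "reports")),
        report_format=options.get("report_format", "csv"),
        log_level=options.get("log_level", "INFO"),
    )
    for table in _TABLE_COLUMNS:
        if table in manifest.inputs:
            p = manifest.path(table)
            if not p.exists():
                raise FileNotFoundError(f"manifest names missing input file: {p}")
        elif table not in _OPTIONAL_TABLES:
            raise MissingInputError(f"manifest missing required input table {table!r}")
    return manifest


@dataclass
class InputBundle:
    """Parsed and cross-checked inputs for a file-based run."""

    cadres: dict[str, Cadre]
    items: dict[str, ResourceItem]
    services: dict[str, ServiceDefinition]
    protocols: dict[str, TreatmentProtocol]
    epi: dict[str, EpidemiologyEntry]
    facilities: list[FacilityDataset]
    census: FacilityTypeCensus | None
    adjustment: AdjustmentFactors | None
    issues: list[Issue] = field(default_factory=list)


def _read_table(path: Path, table: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = _TABLE_COLUMNS[table]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MissingInputError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        log.warning("%s: ignoring unknown column(s) %s", path, extra)
    return df[required]


def _num(value: str, path: Path, row: int, column: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise MissingInputError(
            f"{path}:{row + 2}: malformed number {value!r} in column {column}"
        ) from None


def _flag(value: str) -> bool:
    return str(value).strip().lower() in {"1", "true", "yes", "y"}


def read_inputs(manifest: RunManifest) -> InputBundle:
    """Parse every table named by the manifest and cross-check identifiers.

    Raises on structural problems (missing files/columns, malformed numbers,
    dangling identifiers); per-facility invariant findings are collected on
    ``InputBundle.issues`` instead.
    """
    p = manifest.path("cadres")
    cadres = {
        r.cadre_id: Cadre(
            cadre_id=r.cadre_id, name=r.name,
            annual_remuneration=_num(r.annual_remuneration, p, i, "annual_remuneration"),
            annual_available_minutes=_num(
                r.annual_available_minutes, p, i, "annual_available_minutes"
            ),
            is_technical=_flag(r.is_technical),
        )
        for i, r in enumerate(_read_table(p, "cadres").itertuples())
    }
    p = manifest.path("items")
    items = {
        r.item_id: ResourceItem(
            item_id=r.item_id, name=r.name, category=ItemCategory(r.category),
            unit_price=_num(r.unit_price, p, i, "unit_price"), donated=_flag(r.donated),
        )
        for i, r in enumerate(_read_table(p, "items").itertuples())
    }
    p = manifest.path("services")
    services = {
        r.service_id: ServiceDefinition(
            service_id=r.service_id, name=r.name, program=r.program,
            care_type=CareType(r.care_type), in_bphs=_flag(r.in_bphs),
        )
        for i, r in enumerate(_read_table(p, "services").itertuples())
    }

    p = manifest.path("protocols")
    staff: dict[str, dict[str, float]] = {}
    quantities: dict[str, dict[str, float]] = {}
    for i, r in enumerate(_read_table(p, "protocols").itertuples()):
        amount = _num(r.amount, p, i, "amount")
        if r.service_id not in services:
            raise MissingInputError(f"{p}:{i + 2}: unknown service_id {r.service_id!r}")
        if r.resource_kind == "staff":
            if r.ref_id not in cadres:
                raise MissingInputError(f"{p}:{i + 2}: unknown cadre {r.ref_id!r}")
            staff.setdefault(r.service_id, {})[r.ref_id] = amount
        elif r.resource_kind == "item":
            if r.ref_id not in items:
                raise MissingInputError(f"{p}:{i + 2}: unknown item {r.ref_id!r}")
            quantities.setdefault(r.service_id, {})[r.ref_id] = amount
        else:
            raise MissingInputError(
                f"{p}:{i + 2}: resource_kind must be 'staff' or 'item', got {r.resource_kind!r}"
            )
    protocols = {
        sid: TreatmentProtocol(
            service_id=sid,
            staff_minutes=staff.get(sid, {}),
            item_quantities=quantities.get(sid, {}),
        )
        for sid in set(staff) | set(quantities)
    }

    epi: dict[str, EpidemiologyEntry] = {}
    if "epidemiology" in manifest.inputs:
        p = manifest.path("epidemiology")
        for i, r in enumerate(_read_table(p, "epidemiology").itertuples()):
            epi[r.service_id] = EpidemiologyEntry(
                service_id=r.service_id,
                annual_rate=_num(r.annual_rate, p, i, "annual_rate"),
                rate_kind=RateKind(r.rate_kind),
                source_note=r.source_note,
            )

    p = manifest.path("facilities")
    fac_rows = {
        r.facility_id: (
            FacilityType(r.facility_type), r.province,
            _num(r.catchment_population, p, i, "catchment_population"),
        )
        for i, r in enumerate(_read_table(p, "facilities").itertuples())
    }
    staffing: dict[str, dict[str, float]] = {f: {} for f in fac_rows}
    p = manifest.path("staffing")
    for i, r in enumerate(_read_table(p, "staffing").itertuples()):
        staffing.setdefault(r.facility_id, {})[r.cadre_id] = _num(r.headcount, p, i, "headcount")
    utilization: dict[str, dict[str, float]] = {f: {} for f in fac_rows}
    p = manifest.path("utilization")
    for i, r in enumerate(_read_table(p, "utilization").itertuples()):
        utilization.setdefault(r.facility_id, {})[r.service_id] = _num(
            r.annual_count, p, i, "annual_count"
        )
    expenditure: dict[str, dict[str, float]] = {f: {} for f in fac_rows}
    p = manifest.path("expenditure")
    for i, r in enumerate(_read_table(p, "expenditure").itertuples()):
        expenditure.setdefault(r.facility_id, {})[r.line_item] = _num(r.amount, p, i, "amount")

    facilities = []
    for fid, (ftype, province, population) in fac_rows.items():
        if manifest.population_mode == "normative" and ftype in manifest.normative_population:
            population = manifest.normative_population[ftype]
        facilities.append(
            FacilityDataset(
                facility_id=fid, facility_type=ftype, province=province,
                catchment_population=population,
                staffing=staffing.get(fid, {}),
                utilization=utilization.get(fid, {}),
                expenditure=expenditure.get(fid, {}),
            )
        )

    census = None
    if "census" in manifest.inputs and manifest.national_population:
        p = manifest.path("census")
        census = FacilityTypeCensus(
            counts={
                FacilityType(r.facility_type): _num(r.n_facilities, p, i, "n_facilities")
                for i, r in enumerate(_read_table(p, "census").itertuples())
            },
            national_population=manifest.national_population,
        )

    issues: list[Issue] = []
    for dataset in facilities:
        issues.extend(validate_dataset(dataset, services, protocols, cadres))
    return InputBundle(
        cadres=cadres, items=items, services=services, protocols=protocols,
        epi=epi, facilities=facilities, census=census,
        adjustment=manifest.adjustment, issues=issues,
    )


# ---------------------------------------------------------------------------
# Report writing
# ---------------------------------------------------------------------------


def render_aligned(headers: list[str], rows: list[list[Any]]) -> str:
    """Plain monospaced table rendering (right-aligned numeric columns)."""
    cells = [[str(h) for h in headers]] + [
        [f"{v:,.2f}" if isinstance(v, float) else str(v) for v in row] for row in rows
    ]
    widths = [max(len(r[i]) for r in cells) for i in range(len(headers))]
    lines = []
    for r, row in enumerate(cells):
        lines.append("  ".join(c.rjust(w) for c, w in zip(row, widths)))
        if r == 0:
            lines.append("  ".join("-" * w for w in widths))
    return "\n".join(lines)


def write_unit_costs(path: Path, unit_costs: Mapping[str, ServiceUnitCost]) -> None:
    df = pd.DataFrame(
        [
            {
                "service_id": sid,
                "direct_staff": round_half_up(u.direct_staff_cost, 2),
                "direct_items": round_half_up(u.direct_items_cost, 2),
                "indirect": round_half_up(u.indirect_cost, 2),
                "total": round_half_up(u.total_unit_cost, 2),
            }
            for sid, u in sorted(unit_costs.items())
        ]
    )
    df.to_csv(path, index=False)


def _scenario_rows(analyses: Iterable[FacilityAnalysis]) -> list[dict[str, Any]]:
    rows = []
    for a in analyses:
        for res in (a.actual, a.required, a.optimal):
            if res is None:
                continue
            rows.append(
                {
                    "facility_id": res.facility_id,
                    "scenario": res.scenario.value,
                    "total_cost": round_half_up(res.total_cost, 2),
                    "bphs_cost": round_half_up(res.bphs_cost, 2),
                    "non_bphs_cost": round_half_up(res.non_bphs_cost, 2),
                    "total_volume": round_half_up(res.total_volume, 1),
                    "cost_per_service": (
                        "" if res.cost_per_service is None
                        else round_half_up(res.cost_per_service, 2)
                    ),
                    "cost_per_capita_bphs": round_half_up(res.cost_per_capita_bphs, 2),
                    "cost_per_capita_total": round_half_up(res.cost_per_capita_total, 2),
                }
            )
        if a.gap is not None:
            rows.append(
                {
                    "facility_id": a.dataset.facility_id,
                    "scenario": "gap",
                    "total_cost": a.gap.actual_pct_of_required,
                    "bphs_cost": a.gap.actual_pct_of_optimal_services,
                    "non_bphs_cost": "",
                    "total_volume": "",
                    "cost_per_service": "",
                    "cost_per_capita_bphs": "",
                    "cost_per_capita_total": "",
                }
            )
    return rows


def write_national(path: Path, estimate) -> None:
    rows = []
    for ft, totals in estimate.per_type_totals.items():
        for metric, value in totals.items():
            rows.append({"facility_type": ft.value, "metric": metric, "value": round_half_up(value, 2)})
    for metric, value in estimate.totals.items():
        rows.append({"facility_type": "TOTAL", "metric": metric, "value": round_half_up(value, 2)})
    for metric, value in estimate.per_capita.items():
        rows.append(
            {"facility_type": "TOTAL", "metric": f"{metric}_per_capita", "value": round_half_up(value, 2)}
        )
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class PipelineReport:
    analysis: BundleAnalysis | None
    facility_analyses: list[FacilityAnalysis]
    issues: list[Issue]
    out_dir: Path
    summary: dict[str, Any]


def run_pipeline(manifest: RunManifest) -> PipelineReport:
    """Read inputs, analyze every facility, and write the report set.

    Outputs (under ``manifest.out_dir``): per-facility unit-cost tables,
    a scenario table with one gap row per facility, service rankings, the
    national report when a census is configured, and ``summary.json`` with
    every headline metric.  Deterministic for fixed inputs.
    """
    bundle = read_inputs(manifest)
    errors = [i for i in bundle.issues if i.severity == "error"]
    if errors:
        raise MissingInputError(
            "validation failed: " + "; ".join(i.message for i in errors[:5])
        )
    out = manifest.out_dir if manifest.out_dir.is_absolute() else manifest.base_dir / manifest.out_dir
    out.mkdir(parents=True, exist_ok=True)

    analyses: list[FacilityAnalysis] = []
    rows_by_type: dict[FacilityType, list[dict[str, float]]] = {}
    for dataset in bundle.facilities:
        inputs = FacilityInputs(
            dataset=dataset, services=bundle.services, cadres=bundle.cadres,
            items=bundle.items, protocols=bundle.protocols,
            pool=pool_from_expenditure(dataset),
            epi=bundle.epi, adjustment=bundle.adjustment,
        )
        a = analyze_facility(inputs)
        analyses.append(a)
        write_unit_costs(out / f"unit_costs_{dataset.facility_id}.csv", a.unit_costs)
        costed = {
            sid: (n, n * a.unit_costs[sid].total_unit_cost)
            for sid, n in dataset.utilization.items() if n > 0
        }
        ranked = rank_services(costed, dataset.catchment_population, manifest.top_n)
        pd.DataFrame([r.model_dump() for r in ranked]).to_csv(
            out / f"ranking_{dataset.facility_id}.csv", index=False
        )
        rows_by_type.setdefault(dataset.facility_type, []).append(
            facility_metrics(dataset, a.actual, a.required, bundle.services)
        )

    pd.DataFrame(_scenario_rows(analyses)).to_csv(out / "scenarios.csv", index=False)

    national = None
    if bundle.census is not None:
        summaries = [summarize_type(rows, ft) for ft, rows in rows_by_type.items()]
        national = extrapolate_national(summaries, bundle.census)
        write_national(out / "national.csv", national)

    summary: dict[str, Any] = {
        "n_facilities": len(analyses),
        "actual_total_cost": sum(a.actual.total_cost for a in analyses),
        "required_total_cost": sum(a.required.total_cost for a in analyses),
        "warnings": len([i for i in bundle.issues if i.severity == "warning"]),
    }
    summary["funding_pct"] = round_half_up(
        100.0 * summary["actual_total_cost"] / summary["required_total_cost"]
    )
    if national is not None:
        summary["national_per_capita"] = {
            k: round_half_up(v, 2) for k, v in national.per_capita.items()
        }
        summary["pct_bphs_funded"] = national.pct_bphs_funded
        summary["pct_total_funded"] = national.pct_total_funded
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return PipelineReport(
        analysis=None, facility_analyses=analyses, issues=bundle.issues,
        out_dir=out, summary=summary,
    )


# ---------------------------------------------------------------------------
# Writing a synthetic bundle as an input directory
# ---------------------------------------------------------------------------


def write_bundle_inputs(bundle: SyntheticBundle, directory: str | Path) -> Path:
    """Write a synthetic bundle as a complete input directory.

    Produces every input table, a ``manifest.yaml`` naming them, and
    ``truth.json`` with the injected generator parameters (for parameter-
    recovery tests).  Returns the manifest path.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "cadre_id": c.cadre_id, "name": c.name,
                "annual_remuneration": c.annual_remuneration,
                "annual_available_minutes": c.annual_available_minutes,
                "is_technical": c.is_technical,
            }
            for c in bundle.cadres.values()
        ]
    ).to_csv(d / "cadres.csv", index=False)
    pd.DataFrame(
        [
            {
                "item_id": i.item_id, "name": i.name, "category": i.category.value,
                "unit_price": i.unit_price, "donated": i.donated,
            }
            for i in bundle.items.values()
        ]
    ).to_csv(d / "items.csv", index=False)
    pd.DataFrame(
        [
            {
                "service_id": s.service_id, "name": s.name, "program": s.program,
                "care_type": s.care_type.value, "in_bphs": s.in_bphs,
            }
            for s in bundle.services.values()
        ]
    ).to_csv(d / "services.csv", index=False)
    prot_rows = []
    for pr in bundle.protocols.values():
        for cid, m in pr.staff_minutes.items():
            prot_rows.append(
                {"service_id": pr.service_id, "resource_kind": "staff", "ref_id": cid, "amount": m}
            )
        for iid, q in pr.item_quantities.items():
            prot_rows.append(
                {"service_id": pr.service_id, "resource_kind": "item", "ref_id": iid, "amount": q}
            )
    pd.DataFrame(prot_rows).to_csv(d / "protocols.csv", index=False)
    pd.DataFrame(
        [
            {
                "service_id": e.service_id, "annual_rate": e.annual_rate,
                "rate_kind": e.rate_kind.value, "source_note": e.source_note,
            }
            for e in bundle.epi.values()
        ]
    ).to_csv(d / "epidemiology.csv", index=False)
    pd.DataFrame(
        [
            {
                "facility_id": f.facility_id, "facility_type": f.facility_type.value,
                "province": f.province, "catchment_population": f.catchment_population,
            }
            for f in bundle.facilities
        ]
    ).to_csv(d / "facilities.csv", index=False)
    pd.DataFrame(
        [
            {"facility_id": f.facility_id, "cadre_id": c, "headcount": n}
            for f in bundle.facilities
            for c, n in f.staffing.items()
        ]
    ).to_csv(d / "staffing.csv", index=False)
    pd.DataFrame(
        [
            {"facility_id": f.facility_id, "service_id": s, "annual_count": n}
            for f in bundle.facilities
            for s, n in f.utilization.items()
        ]
    ).to_csv(d / "utilization.csv", index=False)
    pd.DataFrame(
        [
            {"facility_id": f.facility_id, "line_item": li, "amount": v}
            for f in bundle.facilities
            for li, v in f.expenditure.items()
        ]
    ).to_csv(d / "expenditure.csv", index=False)
    pd.DataFrame(
        [
            {"facility_type": ft.value, "n_facilities": n}
            for ft, n in bundle.census.counts.items()
        ]
    ).to_csv(d / "census.csv", index=False)
    (d / "truth.json").write_text(json.dumps(bundle.truth, indent=2, sort_keys=True))
    manifest = {
        "inputs": {t: f"{t}.csv" for t in _TABLE_COLUMNS},
        "options": {
            "population_mode": "actual",
            "national_population": bundle.census.national_population,
            "adjustment": {
                "other_provider_share": {
                    ft.value: v for ft, v in bundle.adjustment.other_provider_share.items()
                },
                "non_access_share": bundle.adjustment.non_access_share,
            },
        },
    }
    (d / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return d / "manifest.yaml"
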