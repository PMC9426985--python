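"""Synthetic input bundles with injected ground truth.

The generator emulates the structure of the 2018 BPHS facility sample: five
facility types (7 mobile teams, 15 of each static type), wide log-uniform
catchment-population ranges, a service catalogue with treatment protocols, an
epidemiological rate table, and annual utilization and expenditure per
facility.

Ground truth is injected by construction:

* utilization is drawn around ``utilization_coverage`` times the adjusted
  epidemiological need (deterministic half-up rounding at ``noise = 0``,
  Poisson at ``noise = 1``, negative-binomial overdispersion above 1);
* actual expenditure is ``funding_ratio`` times the *expected* required cost
  of the facility (the budget is set on expected volumes, so sampling noise
  in realized volumes propagates into the recovered funding ratio).

A pipeline run over the bundle should therefore recover ``funding_ratio``
exactly at ``noise = 0`` and within sampling error otherwise.

Randomness contract: one seed governs a named, ordered family of generators
(one per catalogue section, one per facility slot keyed by type and index), so
enlarging the bundle does not reshuffle earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .costing import IndirectPool, direct_unit_cost, pool_from_expenditure
from .needs import needed_volume
from .types import (
    AdjustmentFactors,
    Cadre,
    CareType,
    EpidemiologyEntry,
    FacilityDataset,
    FacilityType,
    FacilityTypeCensus,
    ItemCategory,
    RateKind,
    ResourceItem,
    ServiceDefinition,
    TreatmentProtocol,
    round_half_up,
)

__all__ = ["SyntheticConfig", "SyntheticBundle", "generate_bundle"]

_SECTION_KEYS = {"cadres": 1, "items": 2, "services": 3, "protocols": 4, "epi": 5}
_TYPE_KEYS = {t: i + 10 for i, t in enumerate(FacilityType)}

_PROGRAMS = (
    "child and adolescent health",
    "reproductive, maternal, and newborn health",
    "communicable diseases",
    "chronic noncommunicable diseases",
    "general curative care",
)


class SyntheticConfig(BaseModel):
    """Generator parameters; defaults mirror the 2018 study conditions."""

    model_config = ConfigDict(frozen=True)

    seed: int = 0
    n_facilities: dict[FacilityType, int] = Field(
        default_factory=lambda: {
            FacilityType.MHT: 7,
            FacilityType.HSC: 15,
            FacilityType.BHC: 15,
            FacilityType.CHC: 15,
            FacilityType.DH: 15,
        }
    )
    population_range: dict[FacilityType, tuple[float, float]] = Field(
        default_factory=lambda: {
            FacilityType.MHT: (1_500, 12_062),
            FacilityType.HSC: (4_320, 11_662),
            FacilityType.BHC: (5_117, 37_590),
            FacilityType.CHC: (12_376, 49_912),
            FacilityType.DH: (8_182, 153_000),
        }
    )
    n_services: int = 30
    n_non_bphs: int = 3
    preventive_fraction: float = Field(default=0.55, ge=0, le=1)
    price_range: tuple[float, float] = (0.10, 25.0)
    remuneration_range: tuple[float, float] = (4_000.0, 15_000.0)
    epi_rate_range: tuple[float, float] = (0.002, 0.40)
    donated_fraction_of_items: float = Field(default=0.3, ge=0, le=1)
    adjustment: AdjustmentFactors = Field(
        default_factory=lambda: AdjustmentFactors(
            other_provider_share={
                FacilityType.MHT: 0.20,
                FacilityType.HSC: 0.20,
                FacilityType.BHC: 0.25,
                FacilityType.CHC: 0.15,
                FacilityType.DH: 0.20,
            },
            non_access_share=0.20,
        )
    )
    funding_ratio: float = Field(default=0.57, ge=0, le=1)
    utilization_coverage: float = Field(default=0.80, ge=0, le=1)
    noise: float = Field(default=1.0, ge=0, description="0 = deterministic; 1 = Poisson; >1 = NB variance factor")
    expenditure_shares: dict[str, float] = Field(
        default_factory=lambda: {
            "medicines": 0.63,
            "technical_salaries": 0.26,
            "support_salaries": 0.06,
            "operating": 0.05,
        }
    )
    donated_fraction_of_medicines: float = Field(default=0.5, ge=0, le=1)
    census_counts: dict[FacilityType, float] = Field(
        default_factory=lambda: {
            FacilityType.MHT: 309,
            FacilityType.HSC: 1_009,
            FacilityType.BHC: 877,
            FacilityType.CHC: 433,
            FacilityType.DH: 85,
        }
    )
    national_population: float = 31_526_403


@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    cadres: dict[str, Cadre]
    items: dict[str, ResourceItem]
    services: dict[str, ServiceDefinition]
    protocols: dict[str, TreatmentProtocol]
    epi: dict[str, EpidemiologyEntry]
    adjustment: AdjustmentFactors
    facilities: list[FacilityDataset]
    census: FacilityTypeCensus
    truth: dict[str, float] = field(default_factory=dict)

    def pool_for(self, dataset: FacilityDataset) -> IndirectPool:
        return pool_from_expenditure(dataset)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *key]))


def _draw_counts(rng: np.random.Generator, expected: np.ndarray, noise: float) -> np.ndarray:
    if noise == 0:
        return np.array([round_half_up(e) for e in expected])
    if noise <= 1:
        return rng.poisson(expected).astype(float)
    # Gamma-Poisson mixture with Var = noise * mean
    shape = expected / (noise - 1.0)
    lam = rng.gamma(np.maximum(shape, 1e-12), noise - 1.0)
    return rng.poisson(lam).astype(float)


def generate_bundle(config: SyntheticConfig) -> SyntheticBundle:
    """Generate one complete, internally consistent input bundle."""
    seed = config.seed

    # --- catalogue ---------------------------------------------------------
    r = _rng(seed, _SECTION_KEYS["cadres"])
    lo, hi = config.remuneration_range
    cadres = {
        "doctor": Cadre(cadre_id="doctor", name="Doctor",
                        annual_remuneration=float(r.uniform(0.7 * hi, hi))),
        "nurse": Cadre(cadre_id="nurse", name="Nurse",
                       annual_remuneration=float(r.uniform(lo, 0.7 * hi))),
        "midwife": Cadre(cadre_id="midwife", name="Midwife",
                         annual_remuneration=float(r.uniform(lo, 0.7 * hi))),
        "support": Cadre(cadre_id="support", name="Support staff",
                         annual_remuneration=float(r.uniform(0.5 * lo, lo)),
                         is_technical=False),
    }
    technical = [c for c in cadres.values() if c.is_technical]

    r = _rng(seed, _SECTION_KEYS["items"])
    n_items = 2 * config.n_services
    plo, phi = config.price_range
    items: dict[str, ResourceItem] = {}
    for i in range(n_items):
        iid = f"item_{i:03d}"
        items[iid] = ResourceItem(
            item_id=iid,
            category=list(ItemCategory)[i % len(ItemCategory)],
            unit_price=float(np.exp(r.uniform(np.log(plo), np.log(phi)))),
            donated=bool(r.random() < config.donated_fraction_of_items),
        )

    r = _rng(seed, _SECTION_KEYS["services"])
    services: dict[str, ServiceDefinition] = {}
    for i in range(config.n_services):
        sid = f"svc_{i:03d}"
        services[sid] = ServiceDefinition(
            service_id=sid,
            name=f"synthetic service {i}",
            program=_PROGRAMS[i % len(_PROGRAMS)],
            care_type=(
                CareType.preventive
                if r.random() < config.preventive_fraction
                else CareType.curative
            ),
            in_bphs=i >= config.n_non_bphs,
        )

    r = _rng(seed, _SECTION_KEYS["protocols"])
    item_ids = list(items)
    protocols: dict[str, TreatmentProtocol] = {}
    for sid in services:
        staff = {
            c.cadre_id: float(r.uniform(2.0, 30.0))
            for c in technical
            if r.random() < 0.7
        }
        if not staff:  # every service needs a technical anchor for allocation
            staff = {technical[0].cadre_id: float(r.uniform(2.0, 30.0))}
        picks = r.choice(len(item_ids), size=r.integers(1, 5), replace=False)
        quantities = {item_ids[int(k)]: float(r.uniform(0.5, 3.0)) for k in picks}
        protocols[sid] = TreatmentProtocol(
            service_id=sid, staff_minutes=staff, item_quantities=quantities
        )

    r = _rng(seed, _SECTION_KEYS["epi"])
    rlo, rhi = config.epi_rate_range
    epi = {
        sid: EpidemiologyEntry(
            service_id=sid,
            annual_rate=float(np.exp(r.uniform(np.log(rlo), np.log(rhi)))),
            rate_kind=(
                RateKind.coverage_target
                if services[sid].care_type is CareType.preventive
                else RateKind.incidence
            ),
            source_note="synthetic",
        )
        for sid in services
    }

    # --- facilities --------------------------------------------------------
    shares = config.expenditure_shares
    support_oper = shares["support_salaries"] + shares["operating"]
    f = config.funding_ratio
    unit_direct = {
        sid: sum(direct_unit_cost(protocols[sid], cadres, items)) for sid in services
    }
    facilities: list[FacilityDataset] = []
    for ftype, n_fac in config.n_facilities.items():
        plo_t, phi_t = config.population_range[ftype]
        for j in range(n_fac):
            r = _rng(seed, _TYPE_KEYS[ftype], j)
            population = float(np.exp(r.uniform(np.log(plo_t), np.log(phi_t))))
            expected = np.array(
                [
                    config.utilization_coverage
                    * needed_volume(population, epi[sid], config.adjustment, ftype).adjusted_need
                    for sid in services
                ]
            )
            counts = _draw_counts(r, expected, config.noise)
            utilization = {
                sid: float(c) for sid, c in zip(services, counts) if c > 0
            }
            # Budget on expected volumes: direct cost of the expected mix,
            # grossed up so that support+operating is its stated share of the
            # actual envelope, then scaled by the funding ratio.
            expected_counts = np.array([round_half_up(e) for e in expected])
            direct_expected = float(
                sum(
                    ec * unit_direct[sid]
                    for sid, ec in zip(services, expected_counts)
                )
            )
            required_expected = direct_expected / (1.0 - support_oper * f)
            actual_total = f * required_expected
            meds = shares["medicines"] * actual_total
            donated = config.donated_fraction_of_medicines * meds
            expenditure = {
                "technical_salaries": shares["technical_salaries"] * actual_total,
                "support_salaries": shares["support_salaries"] * actual_total,
                "medicines_supplies": meds - donated,
                "donated_goods": donated,
                "operating": shares["operating"] * actual_total,
            }
            # headcounts sized to the expected workload
            fte: dict[str, float] = {}
            for sid, ec in zip(services, expected_counts):
                for cid, m in protocols[sid].staff_minutes.items():
                    fte[cid] = fte.get(cid, 0.0) + ec * m
            staffing = {
                cid: float(np.ceil(v / cadres[cid].annual_available_minutes))
                for cid, v in fte.items()
            }
            staffing["support"] = 2.0
            facilities.append(
                FacilityDataset(
                    facility_id=f"{ftype.value.lower()}_{j:02d}",
                    facility_type=ftype,
                    province=f"province_{j:02d}",
                    catchment_population=population,
                    staffing=staffing,
                    utilization=utilization,
                    expenditure=expenditure,
                )
            )

    census = FacilityTypeCensus(
        counts=dict(config.census_counts),
        national_population=config.national_population,
    )
    return SyntheticBundle(
        config=config,
        cadres=cadres,
        items=items,
        services=services,
        protocols=protocols,
        epi=epi,
        adjustment=config.adjustment,
        facilities=facilities,
        census=census,
        truth={
            "funding_ratio": f,
            "utilization_coverage": config.utilization_coverage,
        },
    )
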