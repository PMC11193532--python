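"""Infusion-protocol settings for the three-tracer study design.

The default values are the study protocol: a 2H2O bolus enriching total body
water to 4.5% (with a [6,6-2H2]glucose prime of 440 umol/kg), a continuous
[6,6-2H2]glucose infusion of 4.4 umol/kg/min, and a primed (1.1 mmol/kg)
continuous [U-13C]propionate infusion of 0.055 mmol/kg/min.
"""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass

from .emu import TracerSpec


@dataclass
class Protocol:
    body_water_enrichment: float = 0.045      # steady-state 2H fraction
    water_purity: float = 0.999               # 2H2O isotopic purity
    glucose_infusion_rate: float = 4.4        # umol/kg/min, [6,6-2H2]glucose
    glucose_prime: float = 440.0              # umol/kg
    glucose_purity: float = 0.99
    propionate_infusion_rate: float = 55.0    # umol/kg/min, [U-13C]propionate
    propionate_prime: float = 1100.0          # umol/kg
    propionate_purity: float = 0.99
    body_weight_kg: float = 0.028

    def tracer_specs(self, enriched: bool = True) -> list[TracerSpec]:
        """Tracer configuration for the default liver network.

        With ``enriched=False`` all enrichments are zero, describing the
        pre-infusion baseline sample (natural abundance only).
        """
        e = 1.0 if enriched else 0.0
        return [
            TracerSpec(
                "body_water",
                "Water",
                (("H", 1),),
                purity=self.water_purity,
                enrichment=self.body_water_enrichment * e,
            ),
            TracerSpec(
                "glc_6_6_d2",
                "GlcInf",
                (("H", 6), ("H", 7)),
                purity=self.glucose_purity,
                enrichment=e,
            ),
            TracerSpec(
                "u13c_propionate",
                "Prop",
                (("C", 1), ("C", 2), ("C", 3)),
                purity=self.propionate_purity,
                enrichment=e,
            ),
        ]

    def to_toml(self) -> str:
        lines = ["[protocol]"]
        for k, v in asdict(self).items():
            lines.append(f"{k} = {v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_toml(cls, path) -> "Protocol":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls(**data.get("protocol", data))
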