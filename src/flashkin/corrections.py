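"""Spectral corrections: acceptor-side subtraction and heat-artifact removal.

Two corrections are applied in the flash-FTIR analysis chain:

* **Acceptor-side correction.**  The millisecond DAS of the oxygen-evolving
  S3->S0 transition contains a minor contribution from the two-electron
  quinone chemistry at the acceptor side, which oscillates with flash parity
  (binary oscillation) rather than with S-state period 4.  The same
  acceptor component appears as the 3.1 ms phase of the S1->S2 transition
  (flash 1), so its DAS is subtracted from the S3->S0 millisecond DAS
  pointwise, without further scaling.

* **Heat-artifact correction.**  The exciting flash deposits heat that adds
  a flash-synchronized spectrum to every time sample; it is removed by
  subtracting a reference artifact spectrum (optionally scaled per flash).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dataset import FlashSeriesDataset, SpectrumVector
from .exceptions import ValidationError


@dataclass
class CorrectionRecord:
    """Provenance record of an applied correction."""

    kind: str  # "acceptor_side" | "heat_artifact"
    reference: SpectrumVector
    scaling: float
    provenance: str

    def __post_init__(self):
        if self.kind not in ("acceptor_side", "heat_artifact"):
            raise ValidationError(f"unknown correction kind {self.kind!r}")
        if not np.isfinite(self.scaling):
            raise ValidationError("correction scaling must be finite")
        if self.kind == "acceptor_side" and self.scaling != 1.0:
            raise ValidationError(
                "acceptor-side correction uses fixed unit scaling"
            )


def acceptor_side_correct(
    das_target: SpectrumVector, das_reference: SpectrumVector
) -> tuple[SpectrumVector, CorrectionRecord]:
    """Subtract the acceptor-side reference DAS from a target DAS.

    Pointwise target - reference on identical grids, unit scaling.  Returns
    the corrected spectrum and a provenance record.
    """
    corrected = das_target - das_reference  # grid equality checked by __sub__
    record = CorrectionRecord(
        kind="acceptor_side",
        reference=das_reference,
        scaling=1.0,
        provenance="acceptor-side ms-phase DAS subtracted without scaling",
    )
    return corrected, record


def heat_artifact_correct(
    dataset: FlashSeriesDataset,
    artifact_spectrum: SpectrumVector,
    per_flash_scale=None,
) -> tuple[FlashSeriesDataset, CorrectionRecord]:
    """Remove a flash-synchronized additive artifact spectrum.

    The artifact is modelled as time-independent within each flash record:
    ``scale_n * artifact`` is subtracted from every time sample of flash n.
    ``per_flash_scale`` defaults to 1 for every flash.
    """
    if dataset.wavenumbers != artifact_spectrum.wavenumbers:
        raise ValidationError(
            "artifact spectrum is on a different wavenumber grid than the data"
        )
    n = dataset.n_flashes
    if per_flash_scale is None:
        scales = np.ones(n)
    else:
        scales = np.asarray(per_flash_scale, dtype=float)
        if scales.shape != (n,):
            raise ValidationError(
                f"per_flash_scale must have {n} entries, got {scales.shape}"
            )
        if not np.all(np.isfinite(scales)):
            raise ValidationError("per-flash scales must be finite")
    corrected = dataset.data - (
        scales[:, None, None] * artifact_spectrum.values[None, None, :]
    )
    record = CorrectionRecord(
        kind="heat_artifact",
        reference=artifact_spectrum,
        scaling=1.0,
        provenance=f"time-independent artifact subtracted, scales={scales.tolist()}",
    )
    new = replace(dataset, data=corrected,
                  metadata={**dataset.metadata, "heat_artifact_corrected": True})
    return new, record
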