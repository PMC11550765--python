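"""One-call FOD/FOD-M characterization of a structure model."""

from __future__ import annotations

from dataclasses import dataclass

from .divergence import FodResult, classify, relative_distance
from .envelope import GaussianEnvelope
from .field import DEFAULT_K_GRID, KFit, fit_k, modified_profile
from .profiles import DEFAULT_CUTOFF, Profile, compute_profiles
from .structure import StructureModel

__all__ = ["Analysis", "analyze"]


@dataclass(frozen=True)
class Analysis:
    """Profiles, envelope, RD/K result and classification for one structure."""

    model: StructureModel
    t: Profile
    o: Profile
    r: Profile
    m: Profile
    envelope: GaussianEnvelope
    kfit: KFit
    result: FodResult
    status: str
    environment: str
    cutoff: float
    include_self: bool

    def summary(self) -> dict:
        """JSON-serializable summary of the run."""
        return {
            "id": self.model.id,
            "n_residues": len(self.model),
            "scale_name": self.model.scale_name,
            "cutoff": self.cutoff,
            "include_self": self.include_self,
            "dkl_ot": self.result.dkl_ot,
            "dkl_or": self.result.dkl_or,
            "rd": self.result.rd,
            "k": self.result.k,
            "k_rounded": self.kfit.k_rounded,
            "dkl_om": self.result.dkl_om,
            "k_boundary": self.kfit.boundary,
            "scope": self.result.scope,
            "status": self.status,
            "environment": self.environment,
            "envelope": {
                "center": [float(x) for x in self.envelope.center],
                "sigmas": [float(s) for s in self.envelope.sigmas],
            },
        }


def analyze(
    model: StructureModel,
    cutoff: float = DEFAULT_CUTOFF,
    include_self: bool = True,
    k_grid: tuple[float, float, float] = DEFAULT_K_GRID,
) -> Analysis:
    """Compute T/O/R/M profiles, RD, the fitted K and the environment class."""
    t, o, r, env = compute_profiles(model, cutoff=cutoff, include_self=include_self)
    rd_res = relative_distance(o, t, r)
    kfit = fit_k(o, t, grid=k_grid)
    m = modified_profile(t, kfit.k_opt)
    result = FodResult(
        dkl_ot=rd_res.dkl_ot,
        dkl_or=rd_res.dkl_or,
        rd=rd_res.rd,
        k=kfit.k_opt,
        dkl_om=kfit.dkl_om_min,
        scope="whole",
    )
    status, environment = classify(result.rd, kfit.k_opt)
    return Analysis(
        model=model, t=t, o=o, r=r, m=m, envelope=env, kfit=kfit,
        result=result, status=status, environment=environment,
        cutoff=cutoff, include_self=include_self,
    )
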