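"""Ready-made synthetic cohort recipes.

`young_clinic_spec` emulates the marginal prevalence profile of a large
child/adolescent specialty-clinic tic-disorder sample (n = 529, 24 lifetime
indicators ranging from 0.6% to 99.8% prevalence, including a near-universal
simple-motor-tics indicator that degeneracy filtering must drop), with an
illustrative single-factor-per-group dependency structure.  The dependency
block is a plausible stand-in, not an estimate of any real joint
distribution: it exists so the full pipeline can be exercised end to end on
data with realistic marginals and clustered dependencies.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .cohort import CohortSpec, VariableSpec

__all__ = ["young_clinic_spec", "example_spec_path"]

# (name, lifetime-present count out of 529, factor, loading); factor None =
# independent of every latent group
_YOUNG_PROFILE: list[tuple[str, int, str | None, float]] = [
    ("simple motor tics", 528, None, 0.0),
    ("simple vocal tics", 498, None, 0.0),
    ("complex motor tics", 275, "tic", 0.60),
    ("complex vocal tics", 251, "tic", 0.85),
    ("coprolalia", 113, "tic", 0.75),
    ("copropraxia", 80, "tic", 0.70),
    ("palilalia", 157, "tic", 0.70),
    ("echolalia", 130, "tic", 0.70),
    ("echopraxia", 88, "tic", 0.65),
    ("touching people", 126, "tic", 0.50),
    ("touching objects", 193, "tic", 0.50),
    ("obsessions", 105, "ocd", 0.70),
    ("compulsions", 300, "ocd", 0.70),
    ("anxiety", 149, "ocd", 0.50),
    ("depression", 41, "ocd", 0.50),
    ("substance use disorder", 3, None, 0.0),
    ("premonitory urges", 296, "urge", 0.60),
    ("tic suppression", 391, "urge", 0.60),
    ("hyperactivity", 153, "adhd", 0.80),
    ("inattention", 235, "adhd", 0.75),
    ("self-injurious behavior", 179, "ocd", 0.45),
    ("aggression toward others", 59, "adhd", 0.50),
    ("impulsivity", 317, "adhd", 0.70),
    ("sleep disorders", 117, "adhd", 0.45),
]

_N_PATIENTS = 529


def young_clinic_spec(seed: int = 0) -> CohortSpec:
    """CohortSpec emulating a young specialty-clinic cohort (illustrative).

    Marginals are exact count/529 fractions; the latent correlation is a
    sum of single-factor blocks (rho_ij = loading_i * loading_j within a
    group, 0 across groups), which is positive semidefinite by construction.
    The 99.8%-prevalence simple-motor-tics indicator is flagged degenerate so
    its minority count is exactly 1 and the degeneracy filter removes it.
    """
    k = len(_YOUNG_PROFILE)
    variables = [
        VariableSpec(
            name=name,
            prevalence=count / _N_PATIENTS,
            degenerate=(name == "simple motor tics"),
        )
        for name, count, _, _ in _YOUNG_PROFILE
    ]
    corr = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            _, _, fi, li = _YOUNG_PROFILE[i]
            _, _, fj, lj = _YOUNG_PROFILE[j]
            if fi is not None and fi == fj:
                corr[i, j] = corr[j, i] = li * lj
    return CohortSpec(
        n_patients=_N_PATIENTS,
        variables=variables,
        latent_corr=corr,
        seed=seed,
        cohort_label="young",
    )


def example_spec_path() -> str:
    """Path to the bundled YAML form of :func:`young_clinic_spec`."""
    return str(resources.files("symptomnet") / "specs" / "clinic_young_cohort.yaml")
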