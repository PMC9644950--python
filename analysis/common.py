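"""Study conditions shared by the analysis drivers.

One quadrant phantom stands in for a mid-diaphyseal SR-CT quadrant scan:
default shell geometry (outer radius 600 μm, wall 300 μm, height 400 μm,
2 μm voxels), 200 canals at mixture 0.4/0.3/0.2/0.1
(laminar/longitudinal/radial/oblique), 150 lacunae, grey contrast 200 vs 50
with Gaussian noise sd 10.
"""

from pathlib import Path

from osteovasc import phantom as ph

RESULTS = Path(__file__).resolve().parent.parent / "results"

PHANTOM_SEED = 11
N_CANALS = 200
N_LACUNAE = 150
MIXTURE = (0.4, 0.3, 0.2, 0.1)
SECTOR = (0.0, 90.0)

COHORT_SEED = 7
CLOSING_RADIUS_VOX = 8.0


def build_study_phantom(seed: int = PHANTOM_SEED) -> ph.PhantomVolumes:
    return ph.build_phantom(N_CANALS, MIXTURE, n_lacunae=N_LACUNAE, seed=seed,
                            sector=SECTOR)
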