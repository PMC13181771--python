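"""File-based analysis round trip: generate -> write GRO -> analyze.

Writes a proton-disordered ice Ih crystal to a GRO file, then runs the full
analysis pipeline on that file (as one would on a GROMACS snapshot),
producing the rings/distribution/metrics report bundle plus a POV-Ray
ring-center fingerprint scene.
"""

from pathlib import Path

from ringorder import CrystalSpec, make_ice
from ringorder.config import RunConfig, run_analysis
from ringorder.io import write_gro

workdir = Path("scratch/example_analysis")
workdir.mkdir(parents=True, exist_ok=True)
gro = workdir / "ih_1024.gro"
write_gro(make_ice(CrystalSpec("Ih", (8, 4, 4), seed=42)), gro)
print(f"wrote {gro}")

records = run_analysis(
    RunConfig(
        input_path=str(gro),
        criterion="CA",
        max_ring=10,
        out_dir=str(workdir / "report"),
        export_centers="pov",
    )
)
r = records[0]
print(f"frame {r.frame_index}: n={r.n_waters}  <q>={r.q_mean:.4f}  RSF={r.rsf:.3f}")
print("CA ring counts:", {k: v for k, v in r.ring_counts.items() if v})
print(f"report bundle in {workdir / 'report'} (rings.csv, distribution.csv, metrics.csv, centers_*.pov)")
print(
    "\nThe GRO coordinates survive the 0.001-nm format precision, so the\n"
    "re-read crystal still shows the ideal fingerprint: 2048 hexagons and\n"
    "RSF = 1.0."
)
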