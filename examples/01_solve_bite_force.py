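"""Solve a single static bite: load the packaged planar toy jaw and compute
the bite force and joint reaction at one bite point, gape and reaction
orientation.

The toy has two mirrored vertical bundles totalling 30 N at a 10 mm
in-lever, so at the closed pose the bite force at a point r mm anterior of
the hinge is 300/r N — e.g. 7.5 N at the 40 mm jaw tip.
"""

from importlib import resources

import jawstatics as js

with resources.as_file(
    resources.files("jawstatics").joinpath("data/planar_toy.json")
) as path:
    model = js.load_jaw_model(path)

for label in ("jaw_tip", "posterior_most"):
    sol = js.solve_bite_force(model, label, gape_deg=0.0, orientation=0.0)
    print(
        f"{label:>16}: bite force {sol.bite_force:6.2f} N, "
        f"joint force {sol.joint_force_magnitude:6.2f} N "
        f"({sol.joint_force_orientation_deg:+.1f} deg from vertical)"
    )

# The joint force is what the quadrate-articular joint must bear to keep the
# mandible in equilibrium; with vertical fibers and a vertical bite it points
# straight ventrally and equals muscle force minus bite force.
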