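"""Map photodamage over combined ETC / Rubisco inactivation.

During the middle 20 minutes of the standard protocol the activities of the
electron transport chain (act_j) and of Rubisco (act_c) are clamped to grid
values, imitating stressors that hit the two processes to different degrees.
"""

import numpy as np

from photofvcb import sweep_act_heatmap

grid = np.linspace(0.0, 1.0, 6)
m = sweep_act_heatmap(grid, grid, par=108.0)

header = "act_j\\act_c " + " ".join(f"{c:6.1f}" for c in grid)
print(header)
for aj, row in zip(grid, m):
    print(f"{aj:11.1f} " + " ".join(f"{v:6.3f}" for v in row))

i, j = np.unravel_index(m.argmin(), m.shape)
print(f"\nworst damage (final Aj = {m[i, j]:.3f}) at act_j = {grid[i]:.1f}, "
      f"act_c = {grid[j]:.1f}: a fully active electron chain feeding a "
      "disabled carbon sink overreduces the chain the most.")
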