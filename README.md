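# capnet

Quantitative topology of sheet-like capillary networks from 3D binary
segmentation volumes.

Given a connected binary segmentation (e.g. the lumen of the alveolar
capillary network from serial block-face SEM data), capnet extracts a
spatial graph by topology-preserving thinning, counts the network's
capillary loops via the Euler number (`chi = N_nodes - N_edges`,
loops = `|chi| + 1` for a connected network) and independently via the
cycle basis, and converts counts to a numerical density per mm³. A
digital physical disector (island/bridge events on slice pairs) provides
an independent stereological estimate of the same density, and per-slice
confusion metrics (SEN/SPE/PPV/NPV/DSC) quantify segmentation quality
against a ground truth. Because no real imaging data ships with the
package, a phantom generator produces voxelized lattice tube networks
with exactly known node/edge/loop counts — including controlled
degradations (tube occlusions, enclosed cavities, salt noise) — against
which the whole pipeline is validated.

## Modules

| module | purpose |
| --- | --- |
| `capnet.volio` | TIFF/MetaImage volume I/O, isotropic resampling, hole filling, largest-component selection, subregion extraction |
| `capnet.synthdata` | lattice tube-network phantoms with exact ground-truth topology and degradations |
| `capnet.graphx` | skeletonization, skeleton → spatial multigraph, degree-1 pruning, degree-2 dissolution, DOT/VTK export |
| `capnet.topo` | Euler number, loop counts (two independent routes), numerical density, group comparisons |
| `capnet.disector` | digital physical disector (islands/bridges) density estimate |
| `capnet.segeval` | per-slice segmentation metrics with stack mean ± SD |
| `capnet.pipeline` | end-to-end orchestration, reproducible run directories |

## CLI

```bash
# generate a 5x5 lattice phantom (16 loops) as a multipage TIFF
capnet generate --rows 5 --cols 5 --out phantom/

# end-to-end: postprocess -> skeleton -> graph -> topology report
capnet run --input phantom/phantom.tif --out run/
cat run/summary.json

# stereological verification on the same volume (h_dis = one slice here)
capnet disector --input phantom/phantom.tif --h-dis-um 0.15 --out events.csv

# segmentation quality of a degraded variant against the phantom
capnet evaluate --gt phantom/phantom.tif --seg degraded.tif --out metrics.csv

# percentage deviations between named runs
capnet compare --summary A=runA/summary.json --summary B=runB/summary.json \
    --pair A:B --out comparison.csv
```

Other subcommands: `preprocess` (resample/fill/largest-component),
`graph` (DOT/VTK export), `analyze` (topology report from DOT files).
All randomness is controlled by explicit `--seed` options; repeated runs
with the same seed produce byte-identical reports.

## Conventions

- arrays are (z, y, x); voxel spacing is carried in nm and converted to
  µm/mm only in reports;
- foreground connectivity is 26 in 3D / 8 in 2D, background 6 / 4;
- graphs are undirected multigraphs — parallel edges and self-loops are
  legitimate topology and count toward the Euler number;
- an isolated closed loop is represented as one node with one self-loop
  (`chi = 0`, one loop).
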