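# Limiting equivalent conductances (S cm^2 / equiv, 25 C) used as relative
# ionic mobilities in the generalized Henderson equation.  Values follow the
# standard electrophysiology tables (Barry & Lynch-style); organic
# polyanions without tabulated values (phosphocreatine, nucleotides,
# quaternary lidocaine derivatives) carry generic large-ion estimates.
# Edit freely: species name -> {z: valence, lambda: limiting conductance}.
H:                {z: 1,  lambda: 349.8}
Li:               {z: 1,  lambda: 38.7}
Na:               {z: 1,  lambda: 50.1}
K:                {z: 1,  lambda: 73.5}
Cs:               {z: 1,  lambda: 77.3}
NH4:              {z: 1,  lambda: 73.6}
TEA:              {z: 1,  lambda: 32.7}
TMA:              {z: 1,  lambda: 44.9}
Mg:               {z: 2,  lambda: 53.1}
Ca:               {z: 2,  lambda: 59.5}
Ba:               {z: 2,  lambda: 63.6}
Cl:               {z: -1, lambda: 76.4}
Br:               {z: -1, lambda: 78.1}
F:                {z: -1, lambda: 55.4}
NO3:              {z: -1, lambda: 71.5}
HCO3:             {z: -1, lambda: 44.5}
H2PO4:            {z: -1, lambda: 33.0}
HPO4:             {z: -2, lambda: 57.0}
SO4:              {z: -2, lambda: 80.0}
acetate:          {z: -1, lambda: 40.9}
gluconate:        {z: -1, lambda: 24.3}
glutamate:        {z: -1, lambda: 26.0}
aspartate:        {z: -1, lambda: 27.4}
methanesulfonate: {z: -1, lambda: 48.8}
isethionate:      {z: -1, lambda: 36.7}
HEPES:            {z: -1, lambda: 22.0}
MES:              {z: -1, lambda: 26.8}
EGTA:             {z: -2, lambda: 24.0}
phosphocreatine:  {z: -2, lambda: 25.0}
ATP:              {z: -2, lambda: 24.0}
GTP:              {z: -2, lambda: 24.0}
QX314:            {z: 1,  lambda: 25.0}
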