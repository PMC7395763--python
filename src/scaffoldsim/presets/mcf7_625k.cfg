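# MCF7 (luminal, slow-growing) breast cancer cells cultured in a collagen scaffold (cubic lattice surrogate).
[scaffold]
n_layers = 10
side_mm = 10
young_modulus_kpa = 47
capacity_per_site = 1

[protocol]
duration_h = 240
dt_h = 1
media_change_h = 24
medium_volume_ml = 17

[population]
initial_cells = 625000
cell_volume_mm3 = 4.2e-6
composition = P:1.0

[celltypes]
P = proliferant
Q = quiescent
D = dead

[rules]
dup : P -> P + P, a * min(Glc, O2) / 24
rest : P -> Q, d * (1 - min(Glc, O2))
wake : Q -> P, b * Glc
die : Q -> D, c * (1 - min(Glc, O2))
move : P -> empty + P, e
clear : D -> empty, a / 24
glc_p : P -> U, environment(Glc)
glc_q : Q -> U, environment(Glc)
o2_p : P -> U, environment(O2)
o2_q : Q -> U, environment(O2)
stiffen : P -> U, environment(YM)

[parameters]
a = 0.38
b = 0.005
c = 0.8
d = 0.8
e = 0.008
U_Glu = 16.7e-12
U_O2 = 2.93e-15
U_YM = 32.2
s = 0.5
lox = 3e-06

[diffusion]
d_glucose_mm2_h = 2.412
d_oxygen_mm2_h = 10.8
media_glucose_g_l = 4.5
incubator_oxygen_g_l = 7.2e-3
glucose_boundary = reservoir
oxygen_boundary = dirichlet

[output]
seed = 0
snapshot_hours = 0, 240
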