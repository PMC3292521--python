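# Two-bead residue parameter table, version 1.
# Columns:
#   aa      one-letter amino-acid code
#   b       Calpha--Cbeta bond length, Angstrom (centroid of side-chain atoms
#           incl. Calpha); NA for glycine, which carries no Cbeta bead
#   r       Cbeta bead radius, Angstrom (radius of gyration of side-chain heavy
#           atoms about the centroid, proportionality constant 1.0); NA for Gly
#   theta0  equilibrium Calpha(i-1)-Calpha(i)-Cbeta(i) bend angle, radians
#   h       hydropathy interaction parameter: Kyte-Doolittle shifted by +4.5 so
#           all values are non-negative (dimensionless energy units); also the
#           like-pair Lennard-Jones well depth eps_ii
#   helix_k per-residue helical force constant: affine inversion of the
#           Pace-Scholtz helix propensity P (kcal/mol), K = 3.26 - P, so strong
#           helix formers are stiffest toward helical geometry
#   beta_k  per-residue beta force constant: beta-propensity rank (Kim-Berg-style
#           ordering, strongest formers first) affinely mapped onto the same
#           numeric range [0.10, 3.26] as helix_k
#   q       formal charge at neutral pH: D,E -1; K,R +1; others (incl. His) 0
aa	b	r	theta0	h	helix_k	beta_k	q
A	0.77	0.90	2.10	6.3	3.26	0.93	0
R	2.38	1.80	2.10	0.0	3.05	1.60	1
N	1.45	1.40	2.10	1.0	2.61	0.76	0
D	1.43	1.40	2.10	1.0	2.57	0.43	-1
C	1.16	1.20	2.10	7.0	2.58	2.10	0
Q	1.79	1.50	2.10	1.0	2.87	1.76	0
E	1.77	1.50	2.10	1.0	2.86	0.26	-1
G	NA	NA	2.10	4.1	2.26	0.60	0
H	1.85	1.50	2.10	1.3	2.65	1.10	0
I	1.52	1.50	2.10	9.0	2.85	3.09	0
L	1.54	1.50	2.10	8.3	3.05	1.93	0
K	2.08	1.60	2.10	0.6	3.00	1.43	1
M	1.80	1.60	2.10	6.4	3.02	2.26	0
F	2.05	1.70	2.10	7.3	2.72	2.59	0
P	1.11	1.20	1.95	2.9	0.10	0.10	0
S	1.04	1.10	2.10	3.7	2.76	1.26	0
T	1.17	1.20	2.10	3.8	2.60	3.26	0
W	2.23	1.90	2.10	3.6	2.77	2.43	0
Y	2.26	1.80	2.10	3.2	2.73	2.76	0
V	1.21	1.30	2.10	8.7	2.65	2.93	0
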