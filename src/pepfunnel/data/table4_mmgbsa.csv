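# Published MM/GBSA component table (kcal/mol, standard error of the mean in sem_* columns).
# The Pep16 electrostatic SEM is stored verbatim as printed (114); it is almost certainly a
# typeset artifact of 1.14.  The AD5584 row is a known-flagged fixture: its printed gas sum
# and total binding energy do not reproduce from its own components at 0.05 kcal/mol.
complex_id,e_vdw,sem_vdw,e_ele,sem_ele,g_gb,sem_gb,g_sa,sem_sa,e_gas,sem_gas,g_sol,sem_sol,dg_bind,sem_bind
Pep16-ACSS2,-60.14,0.12,248.63,114,-212.08,1.00,-7.99,0.01,188.58,1.09,-220.07,1.00,-31.48,0.16
AD5584-ACSS2,-39.51,0.10,-246.36,0.46,264.97,0.01,-5.0,0.48,-285.58,0.52,259.94,0.47,-25.94,0.10
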