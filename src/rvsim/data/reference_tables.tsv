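table	key	group	value	reported_fold	units	source
hemodynamics	RV_systolic_pressure	control	20.9		mmHg	catheterization
hemodynamics	RV_systolic_pressure	bleo	42.9	1.10	mmHg	catheterization
hemodynamics	RV_diastolic_pressure	control	2.4		mmHg	catheterization
hemodynamics	RV_diastolic_pressure	bleo	6.7	1.80	mmHg	catheterization
hemodynamics	arterial_elastance	control	0.91		mmHg/ul	catheterization
hemodynamics	arterial_elastance	bleo	2.75	3.00	mmHg/ul	catheterization
hemodynamics	cardiac_output_normalized	control	1.0		-	catheterization
hemodynamics	cardiac_output_normalized	bleo	0.57	-0.43	-	catheterization; midpoint of reported 0.44-0.70
hemodynamics	cardiac_output_normalized	bleo_a6	0.78	-0.20	-	myocyte study
hemodynamics	ejection_fraction	control	69.6		%	catheterization
hemodynamics	ejection_fraction	bleo	39.4	-0.43	%	catheterization
hemodynamics	fractional_shortening	control	46.1		%	echo; not simulated
hemodynamics	fractional_shortening	bleo	20.1	-0.56	%	echo; not simulated
hemodynamics	fractional_shortening	bleo_a6	36.8	-0.22	%	echo; not simulated
hemodynamics	contractility_index	control	129.1		-	catheterization; not simulated
hemodynamics	contractility_index	bleo	56.4	-0.56	-	catheterization; not simulated
parameters	PVR	bleo	1.96	1.96	fold	simulation input
parameters	PVR	bleo_a6	1.96	1.96	fold	simulation input
parameters	CPA	bleo	0.70	0.70	fold	simulation input
parameters	CPA	bleo_a6	0.70	0.70	fold	simulation input
parameters	Con_collagen	bleo	1.69	1.69	normalized force	simulation input
parameters	Con_collagen	bleo_a6	1.69	1.69	normalized force	simulation input
parameters	k_stiff2	bleo	0.46	0.46	MPa/um	simulation input
parameters	k_stiff2	bleo_a6	0.22	0.22	MPa/um	simulation input
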