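study_id	tumor_type	mirna	direction
Huang Y	PTC	miR-221-3p	up
Lassalle	PTC	miR-221-3p	up
Nikiforova	PTC	miR-221-3p	up
Agretti	PTC	miR-221-3p	up
Sheu	PTC	miR-221-3p	up
Pallante	PTC	miR-221-3p	up
He	PTC	miR-221-3p	up
Schwertheim	PTC	miR-221-3p	up
Yip	PTC	miR-221-3p	up
Braun	ATC	miR-221-3p	up
Nikiforova	ATC	miR-221-3p	up
Schwertheim	ATC	miR-221-3p	up
Huang Y	PTC	miR-146b-5p	up
Lassalle	PTC	miR-146b-5p	up
Nikiforova	PTC	miR-146b-5p	up
Agretti	PTC	miR-146b-5p	up
Sheu	PTC	miR-146b-5p	up
He	PTC	miR-146b-5p	up
Schwertheim	PTC	miR-146b-5p	up
Yip	PTC	miR-146b-5p	up
Swierniak	PTC	miR-146b-5p	up
Schwertheim	ATC	miR-146b-5p	up
Huang Y	PTC	miR-222-3p	up
Lassalle	PTC	miR-222-3p	up
Nikiforova	PTC	miR-222-3p	up
Agretti	PTC	miR-222-3p	up
Sheu	PTC	miR-222-3p	up
Pallante	PTC	miR-222-3p	up
Schwertheim	PTC	miR-222-3p	up
Yip	PTC	miR-222-3p	up
Braun	ATC	miR-222-3p	up
Visone	ATC	miR-222-3p	up
Nikiforova	ATC	miR-222-3p	up
Schwertheim	ATC	miR-222-3p	up
Lassalle	PTC	miR-181b-5p	up
Nikiforova	PTC	miR-181b-5p	up
Sheu	PTC	miR-181b-5p	up
Pallante	PTC	miR-181b-5p	up
Schwertheim	PTC	miR-181b-5p	up
Nikiforova	ATC	miR-181b-5p	up
Nikiforova	PTC	miR-155-5p	up
Agretti	PTC	miR-155-5p	up
He	PTC	miR-155-5p	up
Yip	PTC	miR-155-5p	up
Nikiforova	ATC	miR-155-5p	up
Jacques	PTC	miR-34a-5p	up
Huang Y	PTC	miR-34a-5p	up
Lassalle	PTC	miR-34a-5p	up
He	PTC	miR-34a-5p	up
Lassalle	PTC	miR-26a-5p	down
He	PTC	miR-26a-5p	down
Schwertheim	PTC	miR-26a-5p	up
Braun	ATC	miR-26a-5p	down
Visone	ATC	miR-26a-5p	down
Schwertheim	ATC	miR-26a-5p	down
Nikiforova	PTC	miR-224-5p	up
Agretti	PTC	miR-224-5p	up
Pallante	PTC	miR-224-5p	up
Visone	ATC	miR-224-5p	down
Nikiforova	ATC	miR-224-5p	up
He	PTC	miR-138-5p	down
Yip	PTC	miR-138-5p	down
Swierniak	PTC	miR-138-5p	down
Braun	ATC	miR-138-5p	up
Nikiforova	PTC	miR-187-3p	up
Agretti	PTC	miR-187-3p	up
Swierniak	PTC	miR-187-3p	up
Nikiforova	ATC	miR-187-3p	up
Lassalle	PTC	miR-31-5p	up
Nikiforova	PTC	miR-31-5p	up
Yip	PTC	miR-31-5p	up
Pallante	PTC	miR-125b-5p	up
Schwertheim	PTC	miR-125b-5p	up
Braun	ATC	miR-125b-5p	down
Visone	ATC	miR-125b-5p	down
Schwertheim	ATC	miR-125b-5p	down
Braun	ATC	let-7c	down
Visone	ATC	let-7c	down
Schwertheim	ATC	let-7c	down
Braun	ATC	miR-30a-5p	down
Visone	ATC	miR-30a-5p	down
Schwertheim	ATC	miR-30a-5p	down
Braun	ATC	miR-30d	down
Visone	ATC	miR-30d	down
Schwertheim	ATC	miR-30d	down
Lassalle	PTC	miR-29b-3p	up
He	PTC	miR-29b-3p	up
Braun	ATC	miR-29b-3p	down
Visone	ATC	miR-29b-3p	down
Jacques	PTC	miR-29c-3p	up
He	PTC	miR-29c-3p	up
Braun	ATC	miR-29c-3p	down
Pallante	PTC	miR-181a-5p	up
He	PTC	miR-181a-5p	up
Braun	ATC	miR-181a-5p	down
Lassalle	PTC	miR-203a	up
Swierniak	PTC	miR-203a	up
Visone	ATC	miR-203a	down
Lassalle	PTC	miR-21-5p	up
Schwertheim	PTC	miR-21-5p	up
Braun	ATC	miR-21-5p	up
Schwertheim	ATC	miR-21-5p	up
Lassalle	PTC	miR-100-5p	down
Swierniak	PTC	miR-100-5p	down
Braun	ATC	miR-100-5p	down
Lassalle	PTC	miR-130a-3p	down
Swierniak	PTC	miR-130a-3p	down
Braun	ATC	miR-130a-3p	down
Lassalle	PTC	miR-15b-5p	down
Pallante	PTC	miR-15b-5p	down
Braun	ATC	miR-15b-5p	down
Huang Y	PTC	miR-15a-5p	up
Lassalle	PTC	miR-15a-5p	up
Lassalle	PTC	miR-199a-5p	down
Pallante	PTC	miR-199a-5p	down
Braun	ATC	miR-199a-5p	down
Huang Y	PTC	miR-144-5p	down
Swierniak	PTC	miR-144-5p	down
Huang Y	PTC	miR-7-5p	down
Lassalle	PTC	miR-7-5p	down
Braun	ATC	miR-7-5p	down
Jacques	PTC	miR-34b-5p	up
Huang Y	PTC	miR-34b-5p	up
Yip	PTC	miR-34b-5p	down
Braun	ATC	miR-125a-5p	down
Visone	ATC	miR-125a-5p	down
Braun	ATC	miR-138-3p	down
Visone	ATC	miR-138-3p	down
Braun	ATC	miR-145-5p	down
Visone	ATC	miR-145-5p	down
Braun	ATC	miR-151a-5p	down
Visone	ATC	miR-151a-5p	down
Braun	ATC	miR-99a-5p	down
Visone	ATC	miR-99a-5p	down
Braun	ATC	miR-99b-5p	down
Visone	ATC	miR-99b-5p	down
Braun	ATC	let-7a-5p	down
Visone	ATC	let-7a-5p	up
Braun	ATC	let-7f-5p	down
Visone	ATC	let-7f-5p	up
Pallante	PTC	miR-181c-5p	up
He	PTC	miR-181c-5p	up
Jacques	PTC	miR-183-5p	up
Swierniak	PTC	miR-183-5p	up
Pallante	PTC	miR-213	up
He	PTC	miR-213	up
He	PTC	miR-21-3p	up
Swierniak	PTC	miR-21-3p	up
Pallante	PTC	miR-220	up
He	PTC	miR-220	up
Huang Y	PTC	miR-221-5p	up
Swierniak	PTC	miR-221-5p	up
He	PTC	miR-222-5p	up
Swierniak	PTC	miR-222-5p	up
Lassalle	PTC	miR-345-5p	down
He	PTC	miR-345-5p	down
Jacques	PTC	miR-34a-3p	up
Huang Y	PTC	miR-34a-3p	up
Lassalle	PTC	miR-451a	down
Swierniak	PTC	miR-451a	down
Huang Y	PTC	miR-551b-3p	up
Swierniak	PTC	miR-551b-3p	up
Huang Y	PTC	miR-7-2-3p	down
Swierniak	PTC	miR-7-2-3p	down
Swierniak	PTC	let-7d-5p	down
Braun	ATC	let-7d-5p	down
Yip	PTC	miR-130b-3p	down
Braun	ATC	miR-130b-3p	up
Swierniak	PTC	miR-195-5p	down
Braun	ATC	miR-195-5p	down
Swierniak	PTC	miR-204-5p	down
Braun	ATC	miR-204-5p	down
Swierniak	PTC	miR-486-5p	down
Braun	ATC	miR-486-5p	down
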