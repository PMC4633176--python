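reported	canonical
let-7a	let-7a-5p
let-7a-5p	let-7a-5p
let-7c	let-7c
let-7d-5p	let-7d-5p
let-7f	let-7f-5p
let-7f-5p	let-7f-5p
miR-100	miR-100-5p
miR-100-5p	miR-100-5p
miR-125a-5p	miR-125a-5p
miR-125b	miR-125b-5p
miR-125b-5p	miR-125b-5p
miR-130a	miR-130a-3p
miR-130a-3p	miR-130a-3p
miR-130b-3p	miR-130b-3p
miR-138	miR-138-5p
miR-138-3p	miR-138-3p
miR-138-5p	miR-138-5p
miR-144-5p	miR-144-5p
miR-145	miR-145-5p
miR-145-5p	miR-145-5p
miR-146b	miR-146b-5p
miR-146b-5p	miR-146b-5p
miR-151a-5p	miR-151a-5p
miR-155	miR-155-5p
miR-155-5p	miR-155-5p
miR-15a-5p	miR-15a-5p
miR-15b-5p	miR-15b-5p
miR-181a	miR-181a-5p
miR-181a-5p	miR-181a-5p
miR-181b	miR-181b-5p
miR-181b-5p	miR-181b-5p
miR-181c-5p	miR-181c-5p
miR-183-5p	miR-183-5p
miR-187	miR-187-3p
miR-187-3p	miR-187-3p
miR-195-5p	miR-195-5p
miR-199a-5p	miR-199a-5p
miR-203	miR-203a
miR-203a	miR-203a
miR-204-5p	miR-204-5p
miR-21	miR-21-5p
miR-21-3p	miR-21-3p
miR-21-5p	miR-21-5p
miR-213	miR-213
miR-220	miR-220
miR-221	miR-221-3p
miR-221-3p	miR-221-3p
miR-221-5p	miR-221-5p
miR-222	miR-222-3p
miR-222-3p	miR-222-3p
miR-222-5p	miR-222-5p
miR-224	miR-224-5p
miR-224-5p	miR-224-5p
miR-26a	miR-26a-5p
miR-26a-5p	miR-26a-5p
miR-29b	miR-29b-3p
miR-29b-3p	miR-29b-3p
miR-29c	miR-29c-3p
miR-29c-3p	miR-29c-3p
miR-30a	miR-30a-5p
miR-30a-5p	miR-30a-5p
miR-30d	miR-30d
miR-31	miR-31-5p
miR-31-5p	miR-31-5p
miR-345-5p	miR-345-5p
miR-34a	miR-34a-5p
miR-34a-3p	miR-34a-3p
miR-34a-5p	miR-34a-5p
miR-34b	miR-34b-5p
miR-34b-5p	miR-34b-5p
miR-451a	miR-451a
miR-486-5p	miR-486-5p
miR-551b-3p	miR-551b-3p
miR-7	miR-7-5p
miR-7-2-3p	miR-7-2-3p
miR-7-5p	miR-7-5p
miR-99a	miR-99a-5p
miR-99a-5p	miR-99a-5p
miR-99b	miR-99b-5p
miR-99b-5p	miR-99b-5p
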