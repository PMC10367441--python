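subject,item,response
sub-001,1,4
sub-001,2,2
sub-001,3,2
sub-001,4,1
sub-001,5,3
sub-001,6,5
sub-001,7,3
sub-001,8,2
sub-001,9,3
sub-001,10,3
sub-001,11,1
sub-001,12,2
sub-001,13,3
sub-001,14,3
sub-001,15,1
sub-001,16,4
sub-001,17,2
sub-001,18,3
sub-001,19,3
sub-001,20,4
sub-001,21,3
sub-001,22,1
sub-001,23,2
sub-001,24,2
sub-001,25,3
sub-001,26,1
sub-001,27,1
sub-001,28,4
sub-001,29,1
sub-001,30,1
sub-001,31,5
sub-001,32,5
sub-001,33,1
sub-001,34,1
sub-001,35,4
sub-001,36,1
sub-002,1,1
sub-002,2,4
sub-002,3,5
sub-002,4,3
sub-002,5,2
sub-002,6,1
sub-002,7,3
sub-002,8,4
sub-002,9,5
sub-002,10,2
sub-002,11,4
sub-002,12,1
sub-002,13,2
sub-002,14,5
sub-002,15,2
sub-002,16,3
sub-002,17,4
sub-002,18,2
sub-002,19,4
sub-002,20,1
sub-002,21,5
sub-002,22,3
sub-002,23,5
sub-002,24,4
sub-002,25,5
sub-002,26,5
sub-002,27,5
sub-002,28,5
sub-002,29,4
sub-002,30,2
sub-002,31,3
sub-002,32,2
sub-002,33,2
sub-002,34,5
sub-002,35,4
sub-002,36,2
sub-003,1,4
sub-003,2,5
sub-003,3,5
sub-003,4,4
sub-003,5,4
sub-003,6,4
sub-003,7,3
sub-003,8,5
sub-003,9,5
sub-003,10,2
sub-003,11,5
sub-003,12,4
sub-003,13,4
sub-003,14,4
sub-003,15,5
sub-003,16,2
sub-003,17,5
sub-003,18,5
sub-003,19,5
sub-003,20,4
sub-003,21,4
sub-003,22,4
sub-003,23,4
sub-003,24,5
sub-003,25,5
sub-003,26,5
sub-003,27,5
sub-003,28,5
sub-003,29,5
sub-003,30,5
sub-003,31,2
sub-003,32,4
sub-003,33,3
sub-003,34,2
sub-003,35,4
sub-003,36,4
sub-004,1,3
sub-004,2,5
sub-004,3,5
sub-004,4,2
sub-004,5,1
sub-004,6,5
sub-004,7,5
sub-004,8,4
sub-004,9,3
sub-004,10,5
sub-004,11,3
sub-004,12,3
sub-004,13,3
sub-004,14,4
sub-004,15,5
sub-004,16,5
sub-004,17,4
sub-004,18,5
sub-004,19,3
sub-004,20,3
sub-004,21,5
sub-004,22,2
sub-004,23,2
sub-004,24,5
sub-004,25,5
sub-004,26,2
sub-004,27,5
sub-004,28,5
sub-004,29,3
sub-004,30,2
sub-004,31,1
sub-004,32,2
sub-004,33,3
sub-004,34,4
sub-004,35,3
sub-004,36,5
sub-005,1,4
sub-005,2,5
sub-005,3,5
sub-005,4,4
sub-005,5,5
sub-005,6,4
sub-005,7,1
sub-005,8,3
sub-005,9,4
sub-005,10,2
sub-005,11,3
sub-005,12,5
sub-005,13,3
sub-005,14,5
sub-005,15,5
sub-005,16,5
sub-005,17,4
sub-005,18,5
sub-005,19,2
sub-005,20,4
sub-005,21,2
sub-005,22,5
sub-005,23,4
sub-005,24,5
sub-005,25,4
sub-005,26,5
sub-005,27,3
sub-005,28,2
sub-005,29,5
sub-005,30,4
sub-005,31,3
sub-005,32,4
sub-005,33,3
sub-005,34,2
sub-005,35,4
sub-005,36,5
sub-006,1,1
sub-006,2,4
sub-006,3,5
sub-006,4,4
sub-006,5,4
sub-006,6,4
sub-006,7,2
sub-006,8,4
sub-006,9,2
sub-006,10,5
sub-006,11,5
sub-006,12,3
sub-006,13,5
sub-006,14,4
sub-006,15,3
sub-006,16,5
sub-006,17,4
sub-006,18,3
sub-006,19,4
sub-006,20,2
sub-006,21,4
sub-006,22,1
sub-006,23,5
sub-006,24,4
sub-006,25,5
sub-006,26,3
sub-006,27,3
sub-006,28,3
sub-006,29,4
sub-006,30,5
sub-006,31,2
sub-006,32,5
sub-006,33,5
sub-006,34,2
sub-006,35,4
sub-006,36,5
sub-007,1,2
sub-007,2,3
sub-007,3,2
sub-007,4,2
sub-007,5,5
sub-007,6,2
sub-007,7,2
sub-007,8,4
sub-007,9,1
sub-007,10,1
sub-007,11,2
sub-007,12,3
sub-007,13,2
sub-007,14,3
sub-007,15,4
sub-007,16,2
sub-007,17,5
sub-007,18,2
sub-007,19,3
sub-007,20,5
sub-007,21,5
sub-007,22,1
sub-007,23,4
sub-007,24,2
sub-007,25,3
sub-007,26,1
sub-007,27,2
sub-007,28,1
sub-007,29,1
sub-007,30,3
sub-007,31,2
sub-007,32,1
sub-007,33,4
sub-007,34,5
sub-007,35,2
sub-007,36,1
sub-008,1,5
sub-008,2,1
sub-008,3,4
sub-008,4,4
sub-008,5,3
sub-008,6,4
sub-008,7,5
sub-008,8,5
sub-008,9,4
sub-008,10,4
sub-008,11,3
sub-008,12,4
sub-008,13,3
sub-008,14,3
sub-008,15,5
sub-008,16,5
sub-008,17,5
sub-008,18,2
sub-008,19,4
sub-008,20,5
sub-008,21,5
sub-008,22,2
sub-008,23,5
sub-008,24,3
sub-008,25,4
sub-008,26,3
sub-008,27,1
sub-008,28,5
sub-008,29,3
sub-008,30,5
sub-008,31,5
sub-008,32,4
sub-008,33,4
sub-008,34,3
sub-008,35,4
sub-008,36,4
sub-009,1,5
sub-009,2,5
sub-009,3,3
sub-009,4,5
sub-009,5,5
sub-009,6,3
sub-009,7,5
sub-009,8,2
sub-009,9,5
sub-009,10,1
sub-009,11,3
sub-009,12,5
sub-009,13,3
sub-009,14,5
sub-009,15,3
sub-009,16,4
sub-009,17,4
sub-009,18,2
sub-009,19,3
sub-009,20,1
sub-009,21,3
sub-009,22,4
sub-009,23,3
sub-009,24,4
sub-009,25,5
sub-009,26,4
sub-009,27,5
sub-009,28,5
sub-009,29,2
sub-009,30,4
sub-009,31,4
sub-009,32,5
sub-009,33,3
sub-009,34,3
sub-009,35,3
sub-009,36,5
sub-010,1,5
sub-010,2,1
sub-010,3,1
sub-010,4,5
sub-010,5,4
sub-010,6,2
sub-010,7,2
sub-010,8,1
sub-010,9,3
sub-010,10,2
sub-010,11,1
sub-010,12,3
sub-010,13,4
sub-010,14,2
sub-010,15,3
sub-010,16,4
sub-010,17,5
sub-010,18,3
sub-010,19,4
sub-010,20,2
sub-010,21,5
sub-010,22,4
sub-010,23,1
sub-010,24,1
sub-010,25,2
sub-010,26,3
sub-010,27,4
sub-010,28,2
sub-010,29,1
sub-010,30,4
sub-010,31,3
sub-010,32,3
sub-010,33,2
sub-010,34,4
sub-010,35,3
sub-010,36,2
sub-011,1,2
sub-011,2,1
sub-011,3,5
sub-011,4,5
sub-011,5,5
sub-011,6,2
sub-011,7,2
sub-011,8,5
sub-011,9,3
sub-011,10,5
sub-011,11,1
sub-011,12,1
sub-011,13,2
sub-011,14,3
sub-011,15,5
sub-011,16,1
sub-011,17,2
sub-011,18,3
sub-011,19,5
sub-011,20,4
sub-011,21,5
sub-011,22,4
sub-011,23,5
sub-011,24,3
sub-011,25,2
sub-011,26,1
sub-011,27,5
sub-011,28,3
sub-011,29,5
sub-011,30,5
sub-011,31,4
sub-011,32,4
sub-011,33,5
sub-011,34,5
sub-011,35,3
sub-011,36,2
sub-012,1,3
sub-012,2,2
sub-012,3,2
sub-012,4,4
sub-012,5,5
sub-012,6,4
sub-012,7,1
sub-012,8,1
sub-012,9,2
sub-012,10,1
sub-012,11,3
sub-012,12,5
sub-012,13,5
sub-012,14,5
sub-012,15,3
sub-012,16,4
sub-012,17,4
sub-012,18,2
sub-012,19,5
sub-012,20,3
sub-012,21,3
sub-012,22,3
sub-012,23,2
sub-012,24,3
sub-012,25,4
sub-012,26,3
sub-012,27,2
sub-012,28,1
sub-012,29,1
sub-012,30,2
sub-012,31,1
sub-012,32,5
sub-012,33,3
sub-012,34,3
sub-012,35,4
sub-012,36,2
sub-013,1,5
sub-013,2,5
sub-013,3,4
sub-013,4,3
sub-013,5,4
sub-013,6,1
sub-013,7,2
sub-013,8,4
sub-013,9,2
sub-013,10,3
sub-013,11,1
sub-013,12,3
sub-013,13,5
sub-013,14,4
sub-013,15,1
sub-013,16,1
sub-013,17,5
sub-013,18,5
sub-013,19,5
sub-013,20,4
sub-013,21,3
sub-013,22,4
sub-013,23,5
sub-013,24,5
sub-013,25,1
sub-013,26,4
sub-013,27,2
sub-013,28,4
sub-013,29,3
sub-013,30,3
sub-013,31,5
sub-013,32,3
sub-013,33,2
sub-013,34,1
sub-013,35,1
sub-013,36,4
sub-014,1,3
sub-014,2,2
sub-014,3,4
sub-014,4,4
sub-014,5,4
sub-014,6,5
sub-014,7,4
sub-014,8,5
sub-014,9,1
sub-014,10,3
sub-014,11,1
sub-014,12,2
sub-014,13,5
sub-014,14,3
sub-014,15,1
sub-014,16,3
sub-014,17,5
sub-014,18,2
sub-014,19,2
sub-014,20,5
sub-014,21,2
sub-014,22,2
sub-014,23,1
sub-014,24,1
sub-014,25,2
sub-014,26,3
sub-014,27,5
sub-014,28,4
sub-014,29,3
sub-014,30,5
sub-014,31,3
sub-014,32,3
sub-014,33,4
sub-014,34,3
sub-014,35,5
sub-014,36,4
sub-015,1,2
sub-015,2,3
sub-015,3,1
sub-015,4,2
sub-015,5,4
sub-015,6,1
sub-015,7,1
sub-015,8,3
sub-015,9,1
sub-015,10,1
sub-015,11,3
sub-015,12,3
sub-015,13,1
sub-015,14,2
sub-015,15,5
sub-015,16,1
sub-015,17,2
sub-015,18,4
sub-015,19,1
sub-015,20,2
sub-015,21,2
sub-015,22,2
sub-015,23,1
sub-015,24,3
sub-015,25,1
sub-015,26,1
sub-015,27,1
sub-015,28,1
sub-015,29,3
sub-015,30,3
sub-015,31,2
sub-015,32,1
sub-015,33,3
sub-015,34,2
sub-015,35,2
sub-015,36,3
sub-016,1,3
sub-016,2,2
sub-016,3,4
sub-016,4,3
sub-016,5,5
sub-016,6,3
sub-016,7,2
sub-016,8,4
sub-016,9,2
sub-016,10,1
sub-016,11,3
sub-016,12,1
sub-016,13,3
sub-016,14,4
sub-016,15,2
sub-016,16,1
sub-016,17,4
sub-016,18,2
sub-016,19,2
sub-016,20,2
sub-016,21,5
sub-016,22,1
sub-016,23,3
sub-016,24,2
sub-016,25,2
sub-016,26,2
sub-016,27,3
sub-016,28,2
sub-016,29,2
sub-016,30,1
sub-016,31,1
sub-016,32,4
sub-016,33,3
sub-016,34,4
sub-016,35,4
sub-016,36,2
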